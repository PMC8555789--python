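"""Spectrum binning and peptide tokenization.

A spectrum becomes a fixed 80,000-length vector: one 0.1 Da bin per
index (so masses up to 8,000 Da), occupied bins carrying intensities
rescaled to zero mean and unit variance. A peptide string becomes a
64-length sequence of integer tokens over a 30-symbol vocabulary:
the 20 amino acids, nine inline modification characters, and a pad
symbol with id 0. Modification characters ride immediately after the
residue they modify; N-terminal modifications lead the string.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276  # Da, mass of H+ for m/z <-> neutral-mass conversion
WATER_MASS = 18.010565  # Da, monoisotopic H2O

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: inline modification characters: phospho, oxidation, deamidation,
#: carbamidomethyl, acetyl, ammonia-loss, carbamyl, dehydrated, delta-H2C2
MOD_CHARS = "pohcarydt"
PAD_SYMBOL = "_"
DEFAULT_BIN_WIDTH = 0.1     # Da per bin
DEFAULT_MAX_MASS = 8000.0   # Da; 80,000 bins at 0.1 Da
DEFAULT_PAD_LEN = 64


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between the 30 peptide symbols and token ids (pad = 0)."""

    symbol_to_id: Dict[str, int]

    def __post_init__(self):
        ids = sorted(self.symbol_to_id.values())
        if ids != list(range(len(self.symbol_to_id))):
            raise ValueError("token ids must be 0..n-1 with no gaps")
        if len(self.symbol_to_id) != 30:
            raise ValueError(f"vocabulary must have 30 symbols, got {len(self.symbol_to_id)}")

    @classmethod
    def default(cls) -> "Vocabulary":
        mapping = {PAD_SYMBOL: 0}
        for i, aa in enumerate(AMINO_ACIDS, start=1):
            mapping[aa] = i
        for i, m in enumerate(MOD_CHARS, start=21):
            mapping[m] = i
        return cls(mapping)

    @property
    def id_to_symbol(self) -> Dict[int, str]:
        return {v: k for k, v in self.symbol_to_id.items()}

    @property
    def pad_id(self) -> int:
        return self.symbol_to_id[PAD_SYMBOL]

    def __len__(self) -> int:
        return len(self.symbol_to_id)

    def is_mod(self, symbol: str) -> bool:
        return symbol in MOD_CHARS

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for sym, tid in sorted(self.symbol_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{sym}\t{tid}\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        mapping = {}
        with open(path) as fh:
            for line in fh:
                sym, tid = line.rstrip("\n").split("\t")
                mapping[sym] = int(tid)
        return cls(mapping)


@dataclass
class BinnedSpectrum:
    """80,000-length normalized intensity vector plus precursor metadata.

    ``occupied_bins`` records which bins held a peak before
    normalization: an occupied bin whose intensity sits exactly at the
    mean normalizes to 0 and would otherwise be indistinguishable from
    an empty bin.
    """

    vector: np.ndarray
    precursor_neutral_mass: float
    precursor_charge: int
    spectrum_id: str
    occupied_bins: np.ndarray = None

    def __post_init__(self):
        if self.occupied_bins is None:
            self.occupied_bins = np.flatnonzero(self.vector)


@dataclass
class EncodedPeptide:
    """64 right-padded token ids plus the source string and its mass."""

    tokens: np.ndarray
    peptide: str
    monoisotopic_mass: float


def bin_spectrum(spectrum, bin_width: float = DEFAULT_BIN_WIDTH,
                 max_mass: float = DEFAULT_MAX_MASS) -> BinnedSpectrum:
    """Bin a raw spectrum onto the fixed m/z grid and normalize.

    Bin index is floor(m/z / bin_width); peaks beyond the grid are
    dropped; peaks colliding in one bin have their intensities summed.
    Occupied bins are then rescaled to zero mean and unit (population)
    variance — empty bins stay exactly 0, preserving sparsity. A
    spectrum whose occupied bins cannot be scaled (a single peak, or
    identical intensities) is left at 0 in those bins and logged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not spectrum.peaks:
        raise ValueError("empty binned spectrum: no peaks")
    n_bins = int(round(max_mass / bin_width))
    vec = np.zeros(n_bins, dtype=np.float32)
    kept = 0
    for mz, intensity in spectrum.peaks:
        idx = int(mz // bin_width)
        if 0 <= idx < n_bins:
            vec[idx] += intensity
            kept += 1
    if kept == 0:
        raise ValueError("empty binned spectrum: all peaks beyond the bin range")
    nz = np.flatnonzero(vec)
    vals = vec[nz].astype(np.float64)
    sigma = vals.std()  # population convention
    if len(nz) >= 2 and sigma > 0:
        vec[nz] = ((vals - vals.mean()) / sigma).astype(np.float32)
    else:
        logger.debug("spectrum %s: degenerate intensity spread, occupied bins zeroed",
                     spectrum.spectrum_id)
        vec[nz] = 0.0
    neutral = spectrum.precursor_mz * spectrum.precursor_charge \
        - spectrum.precursor_charge * PROTON_MASS
    return BinnedSpectrum(vec, neutral, spectrum.precursor_charge,
                          spectrum.spectrum_id, occupied_bins=nz)


def split_units(peptide: str, vocab: Vocabulary | None = None) -> List[str]:
    """Split a modified peptide into residue units, mods attached.

    "AMoSTK" -> ["A", "Mo", "S", "T", "K"]; N-terminal modification
    characters (those before the first residue) attach to the first
    unit as a prefix: "aPEPK" -> ["aP", "E", "P", "K"].
    """
    vocab = vocab or Vocabulary.default()
    units: List[str] = []
    nterm = ""
    for ch in peptide:
        if ch in AMINO_ACIDS:
            units.append(nterm + ch)
            nterm = ""
        elif vocab.is_mod(ch):
            if not units:
                nterm += ch
            else:
                units[-1] += ch
        else:
            raise ValueError(f"unknown character {ch!r} in peptide {peptide!r}")
    if nterm:
        raise ValueError(f"dangling modification characters in {peptide!r}")
    if not units:
        raise ValueError("peptide must contain at least one residue")
    return units


def encode_peptide(peptide: str, vocab: Vocabulary | None = None,
                   pad_len: int = DEFAULT_PAD_LEN,
                   monoisotopic_mass: float = float("nan")) -> EncodedPeptide:
    """Tokenize a (possibly modified) peptide, right-padded to 64."""
    vocab = vocab or Vocabulary.default()
    if not any(ch in AMINO_ACIDS for ch in peptide):
        raise ValueError("peptide must contain at least one residue")
    ids = []
    for ch in peptide:
        if ch not in vocab.symbol_to_id or ch == PAD_SYMBOL:
            raise ValueError(f"unknown character {ch!r} in peptide {peptide!r}")
        ids.append(vocab.symbol_to_id[ch])
    if len(ids) > pad_len:
        raise ValueError(
            f"peptide too long: {len(ids)} tokens > pad length {pad_len}")
    tokens = np.full(pad_len, vocab.pad_id, dtype=np.int64)
    tokens[:len(ids)] = ids
    return EncodedPeptide(tokens, peptide, monoisotopic_mass)


def decode_peptide(tokens: np.ndarray, vocab: Vocabulary | None = None) -> str:
    """Inverse of :func:`encode_peptide` (pads stripped)."""
    vocab = vocab or Vocabulary.default()
    rev = vocab.id_to_symbol
    out = []
    for tid in np.asarray(tokens):
        if tid == vocab.pad_id:
            continue
        out.append(rev[int(tid)])
    return "".join(out)
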