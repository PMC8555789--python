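"""Embedding-space database search.

Peptide records are embedded once into a mass-sorted index. At query
time each batch of spectra is embedded, candidate peptides are selected
by a precursor-mass window (ppm or Da, inclusive bounds, binary search
over the sorted masses), squared distances are computed with the
Gramian identity over sub-batches of at most 16,384 peptides, and the
five nearest candidates per spectrum are kept. Candidates outside the
window are treated as infinitely distant — never merely multiplied by
zero, which would promote them to perfect scores. The reported match
score is the inverse Euclidean distance 1/L2.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import preprocess
from .digest import PeptideRecord, read_database, write_database
from .model import SiameseEmbedder
from .preprocess import BinnedSpectrum, Vocabulary
from .snaploss import pairwise_sed

SED_FLOOR = 1e-12  # caps 1/L2 for (near-)zero distances


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol: float = 5.0
    tol_unit: str = "ppm"          # "ppm" or "Da"
    top_k: int = 5
    spectrum_batch: int = 1024
    max_peptide_batch: int = 16384

    def __post_init__(self):
        if self.precursor_tol <= 0:
            raise ValueError("precursor tolerance must be positive")
        if self.tol_unit not in ("ppm", "Da"):
            raise ValueError("tol_unit must be 'ppm' or 'Da'")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def window(self, neutral_mass: float):
        """Inclusive [lo, hi] peptide-mass bounds for one precursor."""
        if self.tol_unit == "ppm":
            delta = neutral_mass * self.precursor_tol * 1e-6
        else:
            delta = self.precursor_tol
        return neutral_mass - delta, neutral_mass + delta


@dataclass
class Psm:
    spectrum_id: str
    peptide: str
    is_decoy: bool
    rank: int
    sed: float
    l2_distance: float
    score: float
    precursor_mass: float
    peptide_mass: float
    charge: int


@dataclass
class PeptideIndex:
    """Mass-sorted peptide records with aligned unit-norm embeddings."""

    records: List[PeptideRecord]
    embeddings: np.ndarray
    masses: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.masses is None:
            self.masses = np.asarray(
                [r.monoisotopic_mass for r in self.records], dtype=np.float64)
        if len(self.records) != self.embeddings.shape[0]:
            raise ValueError("records and embeddings misaligned")
        if np.any(np.diff(self.masses) < 0):
            raise ValueError("index must be sorted ascending by mass")

    def __len__(self) -> int:
        return len(self.records)

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "embeddings.npz"),
                 embeddings=self.embeddings, masses=self.masses)
        write_database(self.records, os.path.join(directory, "peptides.tsv"))

    @classmethod
    def load(cls, directory) -> "PeptideIndex":
        with np.load(os.path.join(directory, "embeddings.npz")) as data:
            emb = data["embeddings"]
            masses = data["masses"]
        records = read_database(os.path.join(directory, "peptides.tsv"))
        return cls(records, emb, masses)


def build_index(db: Sequence[PeptideRecord], model: SiameseEmbedder,
                vocab: Optional[Vocabulary] = None,
                batch_size: int = 1024) -> PeptideIndex:
    """Embed every database peptide (eval mode) into a sorted index."""
    if not db:
        raise ValueError("empty peptide database")
    records = sorted(db, key=lambda r: (r.monoisotopic_mass, r.peptide))
    vocab = vocab or Vocabulary.default()
    tokens = np.stack([
        preprocess.encode_peptide(r.peptide, vocab,
                                  pad_len=model.config.pad_len).tokens
        for r in records])
    chunks = [model.embed_peptides(tokens[s:s + batch_size])
              for s in range(0, len(records), batch_size)]
    return PeptideIndex(records, np.vstack(chunks))


def candidate_mask(spectra: Sequence[BinnedSpectrum], index: PeptideIndex,
                   cfg: SearchConfig = SearchConfig()) -> np.ndarray:
    """0/1 matrix (spectra x peptides): 1 inside the precursor window."""
    mask = np.zeros((len(spectra), len(index)), dtype=np.uint8)
    for i, s in enumerate(spectra):
        lo, hi = cfg.window(s.precursor_neutral_mass)
        a = np.searchsorted(index.masses, lo, side="left")
        b = np.searchsorted(index.masses, hi, side="right")
        mask[i, a:b] = 1
    return mask


def search_batch(A: np.ndarray, B: np.ndarray, mask: np.ndarray,
                 cfg: SearchConfig = SearchConfig()) -> np.ndarray:
    """Masked SED matrix: excluded pairs are +inf, never rankable."""
    D = pairwise_sed(A, B)
    if mask.shape != D.shape:
        raise ValueError(f"mask shape {mask.shape} != distance shape {D.shape}")
    D[mask == 0] = np.inf
    return D


def rank_and_score(seds: np.ndarray, candidate_idx: np.ndarray,
                   index: PeptideIndex, spectrum: BinnedSpectrum,
                   cfg: SearchConfig = SearchConfig()) -> List[Psm]:
    """Keep the ``top_k`` nearest candidates of one spectrum as PSMs.

    Ties are broken by lower peptide index; score = 1 / sqrt(SED) with
    the SED floored at 1e-12.
    """
    seds = np.asarray(seds, dtype=np.float64)
    candidate_idx = np.asarray(candidate_idx)
    finite = np.isfinite(seds)
    seds, candidate_idx = seds[finite], candidate_idx[finite]
    if len(seds) == 0:
        return []
    order = np.lexsort((candidate_idx, seds))[:cfg.top_k]
    out = []
    for rank, o in enumerate(order, start=1):
        rec = index.records[int(candidate_idx[o])]
        sed = max(float(seds[o]), SED_FLOOR)
        l2 = float(np.sqrt(sed))
        out.append(Psm(
            spectrum_id=spectrum.spectrum_id, peptide=rec.peptide,
            is_decoy=rec.is_decoy, rank=rank, sed=float(seds[o]),
            l2_distance=l2, score=1.0 / l2,
            precursor_mass=spectrum.precursor_neutral_mass,
            peptide_mass=rec.monoisotopic_mass, charge=spectrum.precursor_charge,
        ))
    return out


def search_spectra(model: SiameseEmbedder, spectra: Sequence[BinnedSpectrum],
                   index: PeptideIndex,
                   cfg: SearchConfig = SearchConfig()) -> List[Psm]:
    """Full search: batch spectra, window candidates, rank top-k PSMs.

    Results are invariant to the 16,384-peptide sub-batching: each
    sub-batch contributes its local top-k and the union is re-ranked,
    which equals the unpartitioned top-k under (distance, index) order.
    """
    psms: List[Psm] = []
    for s0 in range(0, len(spectra), cfg.spectrum_batch):
        batch = spectra[s0:s0 + cfg.spectrum_batch]
        X = np.stack([b.vector for b in batch])
        Q = model.embed_spectra(X)
        mask = candidate_mask(batch, index, cfg)
        # per spectrum: accumulated (sed, peptide index) candidates
        acc_sed = [[] for _ in batch]
        acc_idx = [[] for _ in batch]
        for c0 in range(0, len(index), cfg.max_peptide_batch):
            c1 = min(c0 + cfg.max_peptide_batch, len(index))
            sub = mask[:, c0:c1]
            if not sub.any():
                continue
            D = search_batch(Q, index.embeddings[c0:c1], sub, cfg)
            for i in range(len(batch)):
                cols = np.flatnonzero(np.isfinite(D[i]))
                if len(cols) == 0:
                    continue
                local = cols[np.lexsort((cols, D[i, cols]))[:cfg.top_k]]
                acc_sed[i].extend(D[i, local].tolist())
                acc_idx[i].extend((local + c0).tolist())
        for i, spec in enumerate(batch):
            psms.extend(rank_and_score(acc_sed[i], acc_idx[i], index, spec, cfg))
    return psms
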