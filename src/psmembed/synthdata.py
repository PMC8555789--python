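"""Synthetic labeled (peptide, spectrum) pairs for desk-scale work.

Random tryptic-like peptides (uniform residues, C-terminal K/R) are
fragmented into their b/y ion series:

    b_k = (sum of the first k residue masses) + proton
    y_k = (sum of the last k residue masses) + water + proton

with optional higher fragment charges, Gaussian m/z jitter, random peak
dropout, and uniform noise peaks — enough structure for the encoders to
learn from and none of the intensity physics of a real instrument.
Intensities default to a rank profile (1/r over a random fragment
order): under occupied-bin mean/variance normalization a constant-
intensity spectrum would collapse to the zero vector, so some spread is
required for the spectra to remain informative.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .digest import RESIDUE_MASS, _CHAR_TO_DELTA, peptide_mass
from .io_formats import RawSpectrum
from .preprocess import PROTON_MASS, WATER_MASS, split_units

#: precursor charge frequencies, roughly matching tryptic practice:
#: 2+ dominates, 3+ common, 1+ and 4+ minor.
DEFAULT_CHARGE_PROBS = {1: 0.10, 2: 0.50, 3: 0.30, 4: 0.10}


@dataclass(frozen=True)
class SimulationConfig:
    n_peptides: int = 64
    min_len: int = 7
    max_len: int = 50
    spectra_per_peptide: int = 2
    charge_probs: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGE_PROBS))
    fragment_charges: Tuple[int, ...] = (1,)
    mass_error_sd: float = 0.005   # Da, fragment m/z jitter
    n_noise_peaks: int = 20
    noise_mz_range: Tuple[float, float] = (50.0, 2000.0)
    peak_keep_prob: float = 0.9
    intensity_model: str = "ranks"  # "ranks", "uniform", or "fixed"
    seed: int = 0

    def __post_init__(self):
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if not (1 <= self.min_len <= self.max_len <= 64):
            raise ValueError("length range must satisfy 1 <= min <= max <= 64")
        if not (0 < self.peak_keep_prob <= 1):
            raise ValueError("peak_keep_prob must be in (0, 1]")
        if self.intensity_model not in ("ranks", "uniform", "fixed"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")
        total = sum(self.charge_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("charge probabilities must sum to 1")
        if any(z < 1 for z in self.charge_probs):
            raise ValueError("charges must be >= 1")


def sample_peptides(cfg: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> List[str]:
    """Unique random peptides, uniform residues, last residue K or R."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out: List[str] = []
    seen = set()
    attempts = 0
    max_attempts = 200 * cfg.n_peptides
    while len(out) < cfg.n_peptides:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot draw {cfg.n_peptides} unique peptides in the "
                f"length range [{cfg.min_len}, {cfg.max_len}]")
        length = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        body = "".join(rng.choice(aas, size=length - 1)) if length > 1 else ""
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out


def fragment_mzs(peptide: str,
                 fragment_charges: Sequence[int] = (1,)) -> List[float]:
    """m/z of the full b and y series at the given fragment charges.

    Modified residues shift every fragment containing them by the
    modification delta.
    """
    units = split_units(peptide)
    masses = []
    for unit in units:
        m = RESIDUE_MASS[next(ch for ch in unit if ch in RESIDUE_MASS)]
        m += sum(_CHAR_TO_DELTA[ch] for ch in unit if ch not in RESIDUE_MASS)
        masses.append(m)
    prefix = np.cumsum(masses)
    total = prefix[-1]
    mzs = []
    for k in range(1, len(units)):          # k = 1 .. L-1
        b_neutral = prefix[k - 1]
        y_neutral = total - prefix[len(units) - k - 1] + WATER_MASS
        for z in fragment_charges:
            mzs.append((b_neutral + z * PROTON_MASS) / z)
            mzs.append((y_neutral + z * PROTON_MASS) / z)
    return mzs


def _intensities(n: int, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "fixed":
        return np.ones(n)
    if model == "uniform":
        return rng.uniform(0.2, 1.0, size=n)
    # "ranks": harmonic fall-off over a random fragment order
    ranks = rng.permutation(n)
    return 1.0 / (1.0 + ranks)


def simulate_spectrum(peptide: str, cfg: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      spectrum_id: Optional[str] = None) -> RawSpectrum:
    """One simulated fragmentation spectrum of a peptide."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mzs = np.asarray(fragment_mzs(peptide, cfg.fragment_charges))
    intensities = _intensities(len(mzs), cfg.intensity_model, rng)
    keep = rng.random(len(mzs)) < cfg.peak_keep_prob
    if not keep.any():
        keep[rng.integers(len(mzs))] = True  # never emit a peak-free spectrum
    mzs, intensities = mzs[keep], intensities[keep]
    if cfg.mass_error_sd > 0:
        mzs = mzs + rng.normal(0.0, cfg.mass_error_sd, size=len(mzs))
    peaks = list(zip(mzs.tolist(), intensities.tolist()))
    lo, hi = cfg.noise_mz_range
    for _ in range(cfg.n_noise_peaks):
        peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(0.01, 0.2))))
    charges = sorted(cfg.charge_probs)
    probs = [cfg.charge_probs[z] for z in charges]
    z = int(rng.choice(charges, p=probs))
    neutral = peptide_mass(peptide)
    precursor_mz = (neutral + z * PROTON_MASS) / z
    return RawSpectrum(spectrum_id or f"sim|{peptide}", precursor_mz, z, peaks)


def make_dataset(cfg: SimulationConfig):
    """Labeled pairs [(peptide, spectrum), ...] plus a manifest.

    A pure function of the config: the manifest records every field
    (including the seed) and regenerating from it reproduces the
    dataset exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    peptides = sample_peptides(cfg, rng)
    pairs: List[Tuple[str, RawSpectrum]] = []
    for i, pep in enumerate(peptides):
        for rep in range(cfg.spectra_per_peptide):
            spectrum = simulate_spectrum(
                pep, cfg, rng, spectrum_id=f"syn_{i}_{rep}")
            pairs.append((pep, spectrum))
    manifest = asdict(cfg)
    return pairs, manifest


def dataset_from_manifest(manifest: dict):
    """Regenerate a dataset from its manifest dictionary."""
    cfg_fields = dict(manifest)
    cfg_fields["charge_probs"] = {int(k): v for k, v in
                                  cfg_fields["charge_probs"].items()}
    cfg_fields["fragment_charges"] = tuple(cfg_fields["fragment_charges"])
    cfg_fields["noise_mz_range"] = tuple(cfg_fields["noise_mz_range"])
    return make_dataset(SimulationConfig(**cfg_fields))
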