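"""Reading and writing the surrounding file formats.

MGF peak lists in, FASTA protein databases in, ranked PSM tables out
(plain TSV or a Percolator-compatible pin table). The MGF reader is
deliberately strict about peak lines so that malformed input fails with
a line number instead of silently producing a truncated spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Tuple

import pandas as pd
from pyteomics import fasta as _fasta

PSM_COLUMNS = [
    "spectrum_id", "peptide", "is_decoy", "rank", "l2_distance",
    "score", "precursor_mass", "peptide_mass", "charge",
]

_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class MgfParseError(ValueError):
    """Raised when an MGF block cannot be parsed."""


@dataclass
class RawSpectrum:
    """One MS/MS scan: precursor coordinates plus the fragment peak list.

    Peaks are (m/z, intensity) pairs kept sorted ascending in m/z;
    nonpositive or non-finite entries are rejected at construction.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.precursor_charge < 1:
            raise ValueError(f"precursor charge must be >= 1, got {self.precursor_charge}")
        if not math.isfinite(self.precursor_mz) or self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be finite and > 0, got {self.precursor_mz}")
        clean = []
        for mz, it in self.peaks:
            if math.isfinite(mz) and math.isfinite(it) and mz > 0 and it > 0:
                clean.append((float(mz), float(it)))
        clean.sort(key=lambda p: p[0])
        self.peaks = clean


@dataclass
class ProteinRecord:
    accession: str
    description: str
    sequence: str


def _parse_charge(text: str) -> int:
    """'2+' -> 2, '+2' -> 2, '2' -> 2."""
    t = text.strip().rstrip("+-").lstrip("+")
    try:
        z = int(t)
    except ValueError as exc:
        raise MgfParseError(f"cannot parse CHARGE value {text!r}") from exc
    if z < 1:
        raise MgfParseError(f"CHARGE must be >= 1, got {text!r}")
    return z


def read_mgf(path, default_charge: int = 2) -> Iterator[RawSpectrum]:
    """Stream spectra from an MGF file.

    Spectra missing PEPMASS are skipped with a warning; a missing CHARGE
    line falls back to ``default_charge`` (precursor charge 2 dominates
    typical tryptic data). A malformed peak line raises
    :class:`MgfParseError` naming the offending line number.
    """
    in_block = False
    n_emitted = 0
    title = None
    pepmass = None
    charge = None
    peaks: List[Tuple[float, float]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper() == "BEGIN IONS":
                in_block = True
                title, pepmass, charge, peaks = None, None, None, []
                continue
            if line.upper() == "END IONS":
                in_block = False
                if pepmass is None:
                    warnings.warn(
                        f"spectrum ending at line {lineno} has no PEPMASS; skipped")
                    continue
                n_emitted += 1
                sid = title if title is not None else f"spectrum_{n_emitted}"
                z = charge if charge is not None else default_charge
                yield RawSpectrum(sid, pepmass, z, peaks)
                continue
            if not in_block:
                continue
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.strip().upper()
                if key == "TITLE":
                    title = value.strip()
                elif key == "PEPMASS":
                    # second field, if present, is precursor intensity; ignored
                    pepmass = float(value.split()[0])
                elif key == "CHARGE":
                    charge = _parse_charge(value)
                continue
            fields = line.split()
            try:
                if len(fields) < 2:
                    raise ValueError("expected 'mz intensity'")
                mz, it = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise MgfParseError(
                    f"malformed peak line {lineno}: {line!r}") from exc
            peaks.append((mz, it))


def write_mgf(spectra: Iterable[RawSpectrum], path) -> int:
    """Write spectra as BEGIN IONS/END IONS blocks; returns count written."""
    n = 0
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, it in s.peaks:
                fh.write(f"{mz:.6f} {it:.6f}\n")
            fh.write("END IONS\n")
            n += 1
    return n


def read_fasta(path, on_invalid_residue: str = "raise") -> List[ProteinRecord]:
    """Read protein records; accession is the first header token.

    ``on_invalid_residue``: 'raise' rejects sequences containing letters
    outside the 20 standard amino acids; 'skip' drops such records with
    a warning.
    """
    out: List[ProteinRecord] = []
    with _fasta.read(str(path)) as reader:
        for header, sequence in reader:
            parts = header.split(None, 1)
            accession = parts[0] if parts else ""
            description = parts[1] if len(parts) > 1 else ""
            seq = sequence.strip().upper()
            if not seq:
                raise ValueError(f"empty sequence for accession {accession!r}")
            bad = set(seq) - _AA_LETTERS
            if bad:
                if on_invalid_residue == "skip":
                    warnings.warn(
                        f"{accession}: skipped, non-standard residues {sorted(bad)}")
                    continue
                raise ValueError(
                    f"{accession}: non-standard residues {sorted(bad)}")
            out.append(ProteinRecord(accession, description, seq))
    return out


def _psm_frame(hits) -> pd.DataFrame:
    rows = [{c: getattr(h, c) for c in PSM_COLUMNS} for h in hits]
    df = pd.DataFrame(rows, columns=PSM_COLUMNS)
    if len(df):
        # stable: keep spectra in first-seen order, ranks ascending within
        order = {sid: i for i, sid in enumerate(dict.fromkeys(df["spectrum_id"]))}
        df = df.sort_values(
            by=["spectrum_id", "rank"],
            key=lambda col: col.map(order) if col.name == "spectrum_id" else col,
            kind="stable",
        ).reset_index(drop=True)
    return df


def write_psms(hits, path, dialect: str = "tsv") -> int:
    """Write ranked PSMs; returns the number of rows written.

    'tsv' writes the nine canonical columns. 'percolator-pin' writes a
    Percolator input table: Label +1/-1, plus score, inverse-distance and
    mass-difference features.
    """
    if dialect not in ("tsv", "percolator-pin"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _psm_frame(hits)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return len(df)
    pin = pd.DataFrame({
        "SpecId": [f"{r.spectrum_id}_{r.rank}" for r in df.itertuples()],
        "Label": [-1 if d else 1 for d in df["is_decoy"]],
        "ScanNr": range(1, len(df) + 1),
        "score": df["score"],
        "l2_distance": df["l2_distance"],
        "dM": df["precursor_mass"] - df["peptide_mass"],
        "absdM": (df["precursor_mass"] - df["peptide_mass"]).abs(),
        "rank": df["rank"],
        "Peptide": [f"-.{p}.-" for p in df["peptide"]],
        "Proteins": df["spectrum_id"],
    })
    pin.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(pin)


def read_psms(path) -> list:
    """Read a 'tsv'-dialect PSM table back into Psm objects."""
    from .search import Psm  # local import: search builds on this module's types

    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        out.append(Psm(
            spectrum_id=str(r.spectrum_id), peptide=str(r.peptide),
            is_decoy=bool(r.is_decoy), rank=int(r.rank),
            sed=float(r.l2_distance) ** 2, l2_distance=float(r.l2_distance),
            score=float(r.score), precursor_mass=float(r.precursor_mass),
            peptide_mass=float(r.peptide_mass), charge=int(r.charge),
        ))
    return out
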