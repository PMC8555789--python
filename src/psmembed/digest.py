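"""In-silico tryptic digestion and searchable peptide databases.

Proteins are cleaved C-terminal to K/R (up to two missed cleavages,
7-50 residues by default), variable modifications are enumerated as
inline-character variants, and decoys are produced by reversing the
internal residues of each target — a mass-preserving construction, so
every decoy competes in the same precursor window as its target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

from pyteomics import mass as _pmass
from pyteomics import parser as _pparser

from .preprocess import WATER_MASS, split_units

RESIDUE_MASS: Dict[str, float] = {aa: _pmass.std_aa_mass[aa]
                                  for aa in "ACDEFGHIKLMNPQRSTVWY"}


@dataclass(frozen=True)
class ModificationSpec:
    """A variable modification: inline character, eligible sites, mass."""

    name: str
    character: str
    targets: FrozenSet[str]       # residue letters; empty if N-term only
    mass_delta: float             # Da, monoisotopic
    max_per_peptide: int = 2
    nterm: bool = False


#: Unimod monoisotopic deltas for the nine supported modifications.
DEFAULT_MODIFICATIONS: Dict[str, ModificationSpec] = {
    "phospho": ModificationSpec("phospho", "p", frozenset("STY"), 79.96633),
    "oxidation": ModificationSpec("oxidation", "o", frozenset("MW"), 15.99491),
    "deamidation": ModificationSpec("deamidation", "h", frozenset("NQ"), 0.98402),
    "carbamidomethyl": ModificationSpec("carbamidomethyl", "c", frozenset("C"), 57.02146),
    "acetyl": ModificationSpec("acetyl", "a", frozenset(), 42.01057, nterm=True),
    "ammonia-loss": ModificationSpec("ammonia-loss", "r", frozenset(), -17.02655, nterm=True),
    "carbamyl": ModificationSpec("carbamyl", "y", frozenset(), 43.00581, nterm=True),
    "dehydrated": ModificationSpec("dehydrated", "d", frozenset("ST"), -18.01056),
    "delta-h2c2": ModificationSpec("delta-h2c2", "t", frozenset(), 26.01565, nterm=True),
}

_CHAR_TO_DELTA = {s.character: s.mass_delta for s in DEFAULT_MODIFICATIONS.values()}


@dataclass
class PeptideRecord:
    """One database entry: target or decoy peptide with provenance."""

    peptide: str
    monoisotopic_mass: float
    is_decoy: bool = False
    protein_ids: List[str] = field(default_factory=list)
    missed_cleavages: int = 0


def cleave(sequence: str, max_missed: int = 2, min_len: int = 7,
           max_len: int = 50, suppress_proline: bool = False) -> List[str]:
    """Tryptic peptides of a protein, deduplicated and sorted.

    Cleavage occurs after K and R (optionally suppressed before P);
    windows spanning up to ``max_missed`` internal sites are kept if
    their residue count falls within [min_len, max_len].
    """
    bad = set(sequence) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    rule = r"[KR](?!P)" if suppress_proline else r"[KR]"
    peptides = _pparser.cleave(sequence, rule, missed_cleavages=max_missed,
                               min_length=min_len, max_length=max_len)
    return sorted(peptides)


def count_missed_cleavages(sequence: str, suppress_proline: bool = False) -> int:
    """Internal K/R sites left uncut within one peptide."""
    n = 0
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR" and not (suppress_proline and sequence[i + 1] == "P"):
            n += 1
    return n


def enumerate_modifications(peptide: str,
                            specs: Sequence[ModificationSpec],
                            max_total: int) -> List[str]:
    """All modified variants with at most ``max_total`` modifications.

    A site is one residue position (for residue-targeted specs) or the
    N-terminus; each site carries at most one modification and each
    spec respects its own per-peptide cap. The unmodified peptide is
    always included; output is deduplicated and sorted.
    """
    if max_total < 0:
        raise ValueError("max_total must be >= 0")
    chars = [s.character for s in specs]
    if len(set(chars)) != len(chars):
        raise ValueError("modification characters must be unique among active specs")
    # sites: (position key, spec); position -1 denotes the N-terminus
    sites = []
    for spec in specs:
        if spec.nterm:
            sites.append((-1, spec))
        else:
            for pos, res in enumerate(peptide):
                if res in spec.targets:
                    sites.append((pos, spec))
    variants: Set[str] = {peptide}
    for k in range(1, max_total + 1):
        for combo in itertools.combinations(sites, k):
            positions = [p for p, _ in combo]
            if len(set(positions)) != len(positions):
                continue
            per_spec: Dict[str, int] = {}
            for _, spec in combo:
                per_spec[spec.name] = per_spec.get(spec.name, 0) + 1
            if any(per_spec[s.name] > s.max_per_peptide for _, s in combo):
                continue
            prefix = "".join(s.character for p, s in combo if p == -1)
            out = []
            for pos, res in enumerate(peptide):
                out.append(res)
                out.extend(s.character for p, s in combo if p == pos)
            variants.add(prefix + "".join(out))
    return sorted(variants)


def make_decoy(peptide: str, targets: Optional[Set[str]] = None) -> Optional[str]:
    """Reverse the internal residues, keeping termini fixed.

    Modification characters travel with their residue; N-terminal
    modifications stay at the N-terminus. Returns None if the decoy
    string collides with any peptide in ``targets``.
    """
    units = split_units(peptide)
    if len(units) < 3:
        raise ValueError(f"decoy generation needs >= 3 residues, got {len(units)}")
    decoy = "".join([units[0]] + units[1:-1][::-1] + [units[-1]])
    if targets is not None and decoy in targets:
        return None
    return decoy


def peptide_mass(peptide: str,
                 specs: Optional[Iterable[ModificationSpec]] = None) -> float:
    """Monoisotopic mass: residue masses + water + modification deltas."""
    deltas = (_CHAR_TO_DELTA if specs is None
              else {s.character: s.mass_delta for s in specs})
    total = WATER_MASS
    for unit in split_units(peptide):
        total += RESIDUE_MASS[next(ch for ch in unit if ch in RESIDUE_MASS)]
        for ch in unit:
            if ch in RESIDUE_MASS:
                continue
            if ch not in deltas:
                raise ValueError(f"no mass delta for modification {ch!r}")
            total += deltas[ch]
    return total


def build_database(proteins,
                   specs: Sequence[ModificationSpec] = (),
                   max_total_mods: int = 0,
                   max_missed: int = 2,
                   min_len: int = 7,
                   max_len: int = 50,
                   suppress_proline: bool = False,
                   with_decoys: bool = True) -> List[PeptideRecord]:
    """Digest proteins into a mass-sorted target(+decoy) peptide database."""
    if not proteins:
        raise ValueError("no proteins to digest")
    target_info: Dict[str, dict] = {}
    for prot in proteins:
        for bare in cleave(prot.sequence, max_missed, min_len, max_len,
                           suppress_proline):
            mc = count_missed_cleavages(bare, suppress_proline)
            for variant in enumerate_modifications(bare, specs, max_total_mods):
                info = target_info.setdefault(
                    variant, {"proteins": set(), "mc": mc})
                info["proteins"].add(prot.accession)
    if not target_info:
        raise ValueError("no peptides survive the digestion filters")
    records = [
        PeptideRecord(pep, peptide_mass(pep, specs or None), False,
                      sorted(info["proteins"]), info["mc"])
        for pep, info in target_info.items()
    ]
    if with_decoys:
        target_set = set(target_info)
        mass_of = {r.peptide: r.monoisotopic_mass for r in records}
        seen_decoys: Dict[str, PeptideRecord] = {}
        for pep, info in target_info.items():
            decoy = make_decoy(pep, targets=target_set)
            if decoy is None:
                continue
            if decoy in seen_decoys:
                seen_decoys[decoy].protein_ids = sorted(
                    set(seen_decoys[decoy].protein_ids) | info["proteins"])
                continue
            # internal reversal permutes the residues, so the decoy mass
            # is the target mass exactly — reuse it bit-for-bit
            seen_decoys[decoy] = PeptideRecord(
                decoy, mass_of[pep], True, sorted(info["proteins"]), info["mc"])
        records.extend(seen_decoys.values())
    records.sort(key=lambda r: (r.monoisotopic_mass, r.peptide))
    return records


def write_database(records: Sequence[PeptideRecord], path) -> int:
    with open(path, "w") as fh:
        fh.write("peptide\tmonoisotopic_mass\tis_decoy\tprotein_ids\tmissed_cleavages\n")
        for r in records:
            fh.write(f"{r.peptide}\t{r.monoisotopic_mass:.6f}\t{int(r.is_decoy)}\t"
                     f"{';'.join(r.protein_ids)}\t{r.missed_cleavages}\n")
    return len(records)


def read_database(path) -> List[PeptideRecord]:
    out: List[PeptideRecord] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pep, m, dec, prots, mc = line.rstrip("\n").split("\t")
            out.append(PeptideRecord(pep, float(m), bool(int(dec)),
                                     prots.split(";") if prots else [], int(mc)))
    return out
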