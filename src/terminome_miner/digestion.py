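"""In-silico tryptic digestion, peptide-to-protein mapping and
tryptic-boundary classification.

Trypsin cleaves C-terminal to K or R; with the proline rule on (the
Sequest "Trypsin (full)" convention) cleavage is suppressed when the next
residue is P.  MSFragger's "stricttrypsin" ignores the proline rule, so it
is configurable.

A peptide boundary is "tryptic-compatible" when it could have been produced
by the sample-preparation trypsin: the residue before the peptide is K/R,
or the peptide begins at the database N-terminus (positions 1 or 2 — the
latter covers initiator-methionine removal); symmetrically on the C side.
A semi-tryptic boundary is the evidence for an endogenous cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .io_formats import BOUNDARY, ProteinRecord


@dataclass(frozen=True)
class PeptideLocation:
    """An exact placement of a peptide within one protein (1-based, inclusive)."""

    accession: str
    start: int
    end: int
    prev_aa: str  # '-' at the protein N-terminus
    next_aa: str  # '-' at the protein C-terminus
    unique: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad coordinates {self.start}..{self.end}")


class TrypticClass(str, Enum):
    FULL = "full"
    SEMI_N = "semi_N"
    SEMI_C = "semi_C"
    NON_TRYPTIC = "non_tryptic"


def cleavage_positions(sequence: str, proline_rule: bool = True) -> list[int]:
    """1-based residue indices P1 after which trypsin cuts (interior bonds only)."""
    sites = []
    for i in range(1, len(sequence)):  # bond between residue i and i+1
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P"):
            sites.append(i)
    return sites


def digest_protein(sequence: str, missed_cleavages: int = 0,
                   length_range: tuple[int, int] | None = None,
                   proline_rule: bool = True,
                   accession: str = "") -> list[PeptideLocation]:
    """Enumerate tryptic peptides with up to ``missed_cleavages`` internal sites.

    The length filter is applied last; output is sorted by (start, end).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    bounds = [0] + cleavage_positions(sequence, proline_rule) + [len(sequence)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            start, end = bounds[i] + 1, bounds[j]
            if length_range is not None and not (length_range[0] <= end - start + 1 <= length_range[1]):
                continue
            peptides.append(PeptideLocation(
                accession=accession,
                start=start,
                end=end,
                prev_aa=sequence[start - 2] if start > 1 else BOUNDARY,
                next_aa=sequence[end] if end < len(sequence) else BOUNDARY,
            ))
    return sorted(peptides, key=lambda p: (p.start, p.end))


def map_peptide(peptide: str, proteome: Iterable[ProteinRecord]) -> list[PeptideLocation]:
    """All exact occurrences of ``peptide`` across the proteome.

    ``unique`` is True iff the peptide occurs exactly once in exactly one
    protein.  An empty result means the peptide is unmappable; the caller
    decides whether that is an error.
    """
    if not peptide:
        raise ValueError("empty peptide")
    hits: list[PeptideLocation] = []
    for protein in proteome:
        seq = protein.sequence
        pos = seq.find(peptide)
        while pos != -1:
            start, end = pos + 1, pos + len(peptide)
            hits.append(PeptideLocation(
                accession=protein.accession,
                start=start,
                end=end,
                prev_aa=seq[start - 2] if start > 1 else BOUNDARY,
                next_aa=seq[end] if end < len(seq) else BOUNDARY,
            ))
            pos = seq.find(peptide, pos + 1)
    unique = len(hits) == 1
    return [
        PeptideLocation(h.accession, h.start, h.end, h.prev_aa, h.next_aa, unique)
        for h in hits
    ]


def n_boundary_tryptic(location: PeptideLocation) -> bool:
    """Database N-terminus (start 1 or 2) counts as tryptic-compatible."""
    return location.prev_aa in ("K", "R") or location.start in (1, 2)


def c_boundary_tryptic(location: PeptideLocation, protein_length: int,
                       last_residue: str) -> bool:
    return last_residue in ("K", "R") or location.end == protein_length


def classify_tryptic(location: PeptideLocation, protein: ProteinRecord) -> TrypticClass:
    last = protein.residue(location.end)
    n_ok = n_boundary_tryptic(location)
    c_ok = c_boundary_tryptic(location, len(protein), last)
    if n_ok and c_ok:
        return TrypticClass.FULL
    if c_ok:
        return TrypticClass.SEMI_N
    if n_ok:
        return TrypticClass.SEMI_C
    return TrypticClass.NON_TRYPTIC


def resolve_location(row_proteins: tuple[str, ...], peptide: str,
                     start: int | None, end: int | None,
                     proteome: Mapping[str, ProteinRecord]) -> PeptideLocation | None:
    """Resolve a report row to a unique location, mapping if coordinates are absent.

    Rows listing several proteins, or mapping ambiguously, resolve to None.
    """
    if len(row_proteins) != 1:
        return None
    acc = row_proteins[0]
    protein = proteome.get(acc)
    if protein is None:
        return None
    if start is not None and end is not None:
        if protein.sequence[start - 1:end] != peptide:
            raise ValueError(
                f"{acc}: peptide {peptide} does not match sequence at {start}..{end}")
        return PeptideLocation(
            acc, start, end,
            prev_aa=protein.residue(start - 1),
            next_aa=protein.residue(end + 1),
            unique=True,
        )
    hits = [h for h in map_peptide(peptide, [protein])]
    if len(hits) != 1:
        return None
    return hits[0]
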