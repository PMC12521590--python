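"""Endogenous N-/C-terminus calling from peptide observations.

An N-terminus is called from a peptide whose N-terminal flanking residue is
not K/R (otherwise the boundary is explained by the sample-prep trypsin).
Called N-termini are *mature* when the peptide starts at the database
N-terminus (position 1 or 2) or immediately after the annotated signal
peptide, and *neo* otherwise — neo termini evidence endogenous proteolysis
of the mature protein.  C-termini are symmetric: the peptide's last residue
must not be K/R; peptides ending at the protein's last residue are the
*database* C-terminus and are excluded from neo statistics.

Presence in a sample means a non-missing intensity (identified AND
quantified), counted on raw intensities before any imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .digestion import (PeptideLocation, c_boundary_tryptic, n_boundary_tryptic,
                        resolve_location)
from .io_formats import (PeptideReportRow, PipelineConfig, ProteinRecord,
                         SampleDesign)

MATURE = "mature"
NEO = "neo"
DATABASE = "database"


@dataclass
class TerminusEvent:
    """A called endogenous terminus, merged over supporting peptides."""

    accession: str
    terminus_type: str  # 'N' or 'C'
    category: str  # mature / neo / database
    p1_position: int  # N: start-1; C: end (P1 of the scissile bond)
    p1_prime_residue: str
    peptides: set[str] = field(default_factory=set)
    presence: dict[str, bool] = field(default_factory=dict)
    intensity: dict[str, float] = field(default_factory=dict)
    is_database_terminus: bool = False  # audit flag for start-1/2 mature calls

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.accession, self.terminus_type, self.p1_position)

    def presence_count(self, samples: Iterable[str]) -> int:
        return sum(bool(self.presence.get(s)) for s in samples)


def _presence_from_intensities(intensities: Mapping[str, float]) -> dict[str, bool]:
    return {s: (v is not None and not math.isnan(v)) for s, v in intensities.items()}


def call_n_terminus(row: PeptideReportRow, protein: ProteinRecord,
                    config: PipelineConfig,
                    location: PeptideLocation) -> TerminusEvent | None:
    """Call the N-terminus evidenced by one report row, or None.

    Requires a resolved unique location and peptide FDR at or below the
    configured maximum.  By default the peptide's C boundary must itself be
    tryptic-compatible (pure semi-tryptic evidence); ``allow_non_tryptic``
    relaxes this.
    """
    if row.fdr > config.peptide_fdr_max:
        return None
    if location.prev_aa in ("K", "R"):
        return None  # trypsin artifact
    if not config.allow_non_tryptic:
        last = protein.residue(location.end)
        if not c_boundary_tryptic(location, len(protein), last):
            return None
    start = location.start
    signal_end = protein.signal_end
    if start in (1, 2) or (signal_end is not None and start == signal_end + 1):
        category = MATURE
    else:
        category = NEO
    return TerminusEvent(
        accession=protein.accession,
        terminus_type="N",
        category=category,
        p1_position=start - 1,
        p1_prime_residue=protein.residue(start),
        peptides={row.peptide},
        presence=_presence_from_intensities(row.intensities),
        intensity=dict(row.intensities),
        is_database_terminus=start in (1, 2),
    )


def call_c_terminus(row: PeptideReportRow, protein: ProteinRecord,
                    config: PipelineConfig,
                    location: PeptideLocation) -> TerminusEvent | None:
    """Symmetric C-terminus call; peptides ending in K/R are trypsin artifacts."""
    if row.fdr > config.peptide_fdr_max:
        return None
    last = protein.residue(location.end)
    if last in ("K", "R"):
        return None
    if not config.allow_non_tryptic and not n_boundary_tryptic(location):
        return None
    at_protein_end = location.end == len(protein)
    return TerminusEvent(
        accession=protein.accession,
        terminus_type="C",
        category=DATABASE if at_protein_end else NEO,
        p1_position=location.end,
        p1_prime_residue=protein.residue(location.end + 1),
        peptides={row.peptide},
        presence=_presence_from_intensities(row.intensities),
        intensity=dict(row.intensities),
        is_database_terminus=at_protein_end,
    )


def merge_events(events: Iterable[TerminusEvent]) -> list[TerminusEvent]:
    """Merge events sharing (accession, type, P1): presence OR, intensities summed."""
    merged: dict[tuple[str, str, int], TerminusEvent] = {}
    for ev in events:
        cur = merged.get(ev.key)
        if cur is None:
            merged[ev.key] = TerminusEvent(
                ev.accession, ev.terminus_type, ev.category, ev.p1_position,
                ev.p1_prime_residue, set(ev.peptides), dict(ev.presence),
                dict(ev.intensity), ev.is_database_terminus)
            continue
        cur.peptides |= ev.peptides
        for s, p in ev.presence.items():
            cur.presence[s] = cur.presence.get(s, False) or p
        for s, v in ev.intensity.items():
            if v is None or math.isnan(v):
                cur.intensity.setdefault(s, math.nan)
            else:
                old = cur.intensity.get(s, math.nan)
                cur.intensity[s] = v if (old is None or math.isnan(old)) else old + v
    return sorted(merged.values(), key=lambda e: e.key)


def call_termini(rows: Iterable[PeptideReportRow],
                 proteome: Mapping[str, ProteinRecord],
                 design: SampleDesign,
                 config: PipelineConfig) -> tuple[list[TerminusEvent], list[TerminusEvent], dict]:
    """Call and merge N- and C-termini over a whole report.

    Returns (n_events, c_events, counters); rows without a unique resolved
    location are skipped and counted.
    """
    n_raw: list[TerminusEvent] = []
    c_raw: list[TerminusEvent] = []
    counters = {"rows": 0, "skipped_ambiguous": 0, "skipped_fdr": 0}
    for row in rows:
        counters["rows"] += 1
        if row.fdr > config.peptide_fdr_max:
            counters["skipped_fdr"] += 1
            continue
        location = resolve_location(row.proteins, row.peptide, row.start, row.end, proteome)
        if location is None or not location.unique:
            counters["skipped_ambiguous"] += 1
            continue
        protein = proteome[location.accession]
        ev_n = call_n_terminus(row, protein, config, location)
        if ev_n is not None:
            n_raw.append(ev_n)
        ev_c = call_c_terminus(row, protein, config, location)
        if ev_c is not None:
            c_raw.append(ev_c)
    return merge_events(n_raw), merge_events(c_raw), counters


# ---------------------------------------------------------------------------
# filters and partitions
# ---------------------------------------------------------------------------

def presence_filter(events: Iterable[TerminusEvent], design: SampleDesign,
                    min_count: int) -> list[TerminusEvent]:
    """Keep events present in at least ``min_count`` samples of some group."""
    kept = []
    for ev in events:
        if any(ev.presence_count(design.members(g)) >= min_count for g in design.groups):
            kept.append(ev)
    return kept


def exclusivity_label(event: TerminusEvent, design: SampleDesign,
                      fraction: float) -> str:
    """exclusive_<G> / shared / neither, at the given within-group fraction."""
    a, b = design.groups
    na = event.presence_count(design.members(a))
    nb = event.presence_count(design.members(b))
    need_a = math.ceil(fraction * len(design.members(a)))
    need_b = math.ceil(fraction * len(design.members(b)))
    if na >= need_a and nb == 0:
        return f"exclusive_{a}"
    if nb >= need_b and na == 0:
        return f"exclusive_{b}"
    if na > 0 and nb > 0:
        return "shared"
    return "neither"


@dataclass
class VennPartition:
    """Disjoint common / exclusive-A / exclusive-B partition of features."""

    common: set
    exclusive_a: set
    exclusive_b: set
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if (self.common & self.exclusive_a or self.common & self.exclusive_b
                or self.exclusive_a & self.exclusive_b):
            raise ValueError("Venn partition sets must be pairwise disjoint")

    @property
    def sizes(self) -> dict[str, int]:
        return {"common": len(self.common),
                f"exclusive_{self.label_a}": len(self.exclusive_a),
                f"exclusive_{self.label_b}": len(self.exclusive_b)}

    @property
    def total(self) -> int:
        return len(self.common) + len(self.exclusive_a) + len(self.exclusive_b)


def partition_venn(present_a: set, present_b: set,
                   label_a: str = "A", label_b: str = "B") -> VennPartition:
    return VennPartition(
        common=present_a & present_b,
        exclusive_a=present_a - present_b,
        exclusive_b=present_b - present_a,
        label_a=label_a, label_b=label_b,
    )


def events_venn(events: Iterable[TerminusEvent], design: SampleDesign) -> VennPartition:
    a, b = design.groups
    present_a = {e.key for e in events if e.presence_count(design.members(a)) > 0}
    present_b = {e.key for e in events if e.presence_count(design.members(b)) > 0}
    return partition_venn(present_a, present_b, a, b)


def filter_master_proteins(protein_table: pd.DataFrame, config: PipelineConfig,
                           contaminants: set[str] | frozenset[str] = frozenset()
                           ) -> pd.DataFrame:
    """Master-protein filter: unique-peptide count, identification FDR, contaminants.

    Expects columns ``accession``, ``unique_peptides``, ``fdr``.
    """
    mask = (
        (protein_table["unique_peptides"] >= config.min_unique_peptides)
        & (protein_table["fdr"] <= config.protein_fdr_max)
        & ~protein_table["accession"].isin(contaminants)
    )
    return protein_table.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def events_to_frame(events: Iterable[TerminusEvent], design: SampleDesign,
                    config: PipelineConfig) -> pd.DataFrame:
    """One row per event: category, P1, presence, exclusivity labels.

    Per-sample presence columns make the table a faithful intermediate:
    :func:`events_from_frame` reconstructs the events for later stages.
    """
    a, b = design.groups
    records = []
    for ev in events:
        rec = {
            "accession": ev.accession,
            "terminus_type": ev.terminus_type,
            "category": ev.category,
            "p1_position": ev.p1_position,
            "p1_prime_residue": ev.p1_prime_residue,
            "peptides": ";".join(sorted(ev.peptides)),
            f"n_present_{a}": ev.presence_count(design.members(a)),
            f"n_present_{b}": ev.presence_count(design.members(b)),
            "exclusivity_50": exclusivity_label(ev, design, config.exclusivity_fraction),
            "exclusivity_75": exclusivity_label(ev, design, config.specificity_fraction),
            "is_database_terminus": ev.is_database_terminus,
        }
        for s in design.samples:
            rec[f"present_{s}"] = int(bool(ev.presence.get(s)))
        records.append(rec)
    cols = ["accession", "terminus_type", "category", "p1_position",
            "p1_prime_residue", "peptides", f"n_present_{a}", f"n_present_{b}",
            "exclusivity_50", "exclusivity_75", "is_database_terminus"] + \
           [f"present_{s}" for s in design.samples]
    return pd.DataFrame.from_records(records, columns=cols)


def events_from_frame(frame: pd.DataFrame, design: SampleDesign) -> list[TerminusEvent]:
    """Rebuild events from an ``events_to_frame`` table (intensities omitted)."""
    events = []
    for _, r in frame.iterrows():
        events.append(TerminusEvent(
            accession=str(r["accession"]),
            terminus_type=str(r["terminus_type"]),
            category=str(r["category"]),
            p1_position=int(r["p1_position"]),
            p1_prime_residue=str(r["p1_prime_residue"]),
            peptides=set(str(r["peptides"]).split(";")) if r["peptides"] else set(),
            presence={s: bool(r[f"present_{s}"]) for s in design.samples},
            is_database_terminus=bool(r["is_database_terminus"]),
        ))
    return events


def events_intensity_matrix(events: Iterable[TerminusEvent],
                            design: SampleDesign) -> pd.DataFrame:
    """Terminus-level intensity matrix (features x samples, raw scale, NaN = missing)."""
    index, data = [], []
    for ev in events:
        index.append(f"{ev.accession}:{ev.terminus_type}{ev.p1_position}")
        data.append([ev.intensity.get(s, math.nan) for s in design.samples])
    return pd.DataFrame(data, index=index, columns=design.samples)
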