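"""Cleavage-window extraction, positional residue preferences (logo data),
known-site annotation and protease enrichment.

Windows follow the Schechter-Berger convention: P5..P1 precede the scissile
bond, P1'..P5' follow it; positions falling outside the protein are padded
with 'X' and pads are excluded from frequency denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust
from .io_formats import AMINO_ACIDS, CleavageSiteRecord, ProteinRecord
from .terminome import TerminusEvent

PAD = "X"


def position_labels(half_width: int = 5) -> list[str]:
    return ([f"P{i}" for i in range(half_width, 0, -1)]
            + [f"P{i}'" for i in range(1, half_width + 1)])


def extract_window(protein: ProteinRecord, p1_position: int,
                   half_width: int = 5) -> str:
    """Residues P<hw>..P1, P1'..P<hw>' around the scissile bond after P1.

    ``p1_position`` must be an interior bond (1 <= p1 <= len - 1); database
    termini are excluded upstream.
    """
    if not (1 <= p1_position <= len(protein) - 1):
        raise ValueError(
            f"p1_position {p1_position} not an interior bond of "
            f"{protein.accession} (length {len(protein)})")
    residues = []
    for pos in range(p1_position - half_width + 1, p1_position + half_width + 1):
        r = protein.residue(pos)
        residues.append(r if r != "-" else PAD)
    return "".join(residues)


@dataclass
class PositionFrequencyMatrix:
    """Counts and frequencies of residues per window position (pads excluded)."""

    counts: pd.DataFrame  # positions x 20 residues, integer counts
    n_windows: int

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)

    def top_residues(self) -> pd.Series:
        return self.frequencies.idxmax(axis=1)

    def to_logo_frame(self) -> pd.DataFrame:
        """Long-format (position, residue, frequency, information bits)."""
        freq = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = (np.log2(20) + (freq * np.log2(freq.where(freq > 0))).sum(axis=1))
        rows = []
        for pos in freq.index:
            for res in freq.columns:
                rows.append({"position": pos, "residue": res,
                             "frequency": freq.loc[pos, res],
                             "bits": freq.loc[pos, res] * max(ic[pos], 0.0)})
        return pd.DataFrame(rows)


def build_pfm(windows: Sequence[str], half_width: int = 5) -> PositionFrequencyMatrix:
    if not windows:
        raise ValueError("no windows to profile")
    labels = position_labels(half_width)
    counts = pd.DataFrame(0, index=labels, columns=list(AMINO_ACIDS))
    for w in windows:
        if len(w) != 2 * half_width:
            raise ValueError(f"window {w!r} has length {len(w)}, expected {2 * half_width}")
        for label, res in zip(labels, w):
            if res != PAD:
                counts.loc[label, res] += 1
    return PositionFrequencyMatrix(counts=counts, n_windows=len(windows))


def windows_for_events(events: Iterable[TerminusEvent],
                       proteome: Mapping[str, ProteinRecord],
                       half_width: int = 5,
                       categories: tuple[str, ...] = ("neo",)) -> list[str]:
    """Extract windows for events of the given categories (database termini
    have no interior scissile bond and are skipped)."""
    out = []
    for ev in events:
        if ev.category not in categories:
            continue
        protein = proteome.get(ev.accession)
        if protein is None:
            continue
        if 1 <= ev.p1_position <= len(protein) - 1:
            out.append(extract_window(protein, ev.p1_position, half_width))
    return out


# ---------------------------------------------------------------------------
# known-site annotation and protease enrichment
# ---------------------------------------------------------------------------

NOVEL = "novel"


def match_known_sites(events: Iterable[TerminusEvent],
                      cleavage_db: Iterable[CleavageSiteRecord]
                      ) -> dict[tuple[str, str, int], list[str]]:
    """Exact join of events on (accession, P1); unmatched events are 'novel'."""
    by_site: dict[tuple[str, int], list[str]] = {}
    for rec in cleavage_db:
        by_site.setdefault((rec.accession, rec.p1_position), []).append(rec.protease)
    out: dict[tuple[str, str, int], list[str]] = {}
    for ev in events:
        proteases = by_site.get((ev.accession, ev.p1_position))
        out[ev.key] = sorted(proteases) if proteases else [NOVEL]
    return out


@dataclass
class ProteaseEnrichmentResult:
    protease: str
    k: int  # annotated in foreground
    n: int  # foreground size
    K: int  # annotated in universe (background u foreground)
    N: int  # universe size
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.k <= self.n and self.k <= self.K and self.K <= self.N):
            raise ValueError("inconsistent enrichment counts")


def protease_enrichment(foreground: Sequence[TerminusEvent],
                        background: Sequence[TerminusEvent],
                        cleavage_db: Iterable[CleavageSiteRecord]
                        ) -> list[ProteaseEnrichmentResult]:
    """One-sided hypergeometric enrichment of each protease's annotations in
    the foreground relative to the full termini universe.

    The universe is foreground + background (deduplicated on the event key);
    proteases with no annotation anywhere are omitted; q-values are BH
    across proteases.
    """
    if not foreground:
        raise ValueError("empty foreground")
    db = list(cleavage_db)
    fore_keys = {e.key for e in foreground}
    universe = {e.key: e for e in list(background) + list(foreground)}
    annotations = match_known_sites(universe.values(), db)
    proteases = sorted({p for ann in annotations.values() for p in ann if p != NOVEL})
    N, n = len(universe), len(fore_keys)
    results = []
    for prot in proteases:
        annotated = {k for k, ann in annotations.items() if prot in ann}
        K = len(annotated)
        k = len(annotated & fore_keys)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(ProteaseEnrichmentResult(prot, k, n, K, N, p))
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return sorted(results, key=lambda r: r.p)


def enrichment_to_frame(results: Sequence[ProteaseEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [(r.protease, r.k, r.n, r.K, r.N, r.p, r.q) for r in results],
        columns=["protease", "k_foreground", "n_foreground",
                 "K_universe", "N_universe", "p", "q_bh"])


def compare_group_preferences(pfm_a: PositionFrequencyMatrix,
                              pfm_b: PositionFrequencyMatrix) -> pd.DataFrame:
    """Per-position residue log2 frequency ratios between two groups.

    Pseudo-frequency eps = 1 / (2 * min window count) regularizes zeros;
    swapping the groups negates every entry.
    """
    fa, fb = pfm_a.frequencies, pfm_b.frequencies
    if not fa.index.equals(fb.index):
        raise ValueError("PFMs must share the same position set")
    eps = 1.0 / (2.0 * min(pfm_a.n_windows, pfm_b.n_windows))
    return np.log2((fa + eps) / (fb + eps))
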