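"""Ground-truth degradome cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
groups of subjects, a proteome with and without signal peptides, fully
tryptic peptides from sample-preparation digestion, semi-tryptic peptides
whose non-tryptic boundary marks an endogenous protease cleavage planted
with a positional specificity model and group-dependent occurrence rates,
log-normal intensities with group effects, intensity-dependent missingness,
and a configurable floor of spurious (decoy) semi-tryptic boundaries.

Protein sequences use a uniform residue composition; candidate cleavage
sites are then accepted by thinning with the specificity model's
likelihood ratio, so the residue distribution of accepted sites equals the
specificity model exactly — which makes positional-preference recovery
quantitatively testable.

All randomness flows from ``SimulationConfig.seed`` through named
integer-indexed substreams, so outputs are identical across runs and
platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleavage_profile import position_labels
from .digestion import cleavage_positions, digest_protein
from .io_formats import (AMINO_ACIDS, PeptideReportRow, ProteinRecord,
                         SampleDesign, write_design, write_fasta,
                         write_peptide_report, write_signal_table)

_RES_INDEX = {r: i for i, r in enumerate(AMINO_ACIDS)}
_N_RES = len(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# specificity models
# ---------------------------------------------------------------------------

@dataclass
class SpecificityModel:
    """Positional residue preferences of a protease over P5..P1, P1'..P5'.

    ``log_odds`` maps each of the 10 position labels to a length-20 score
    vector; the implied residue distribution at a position is
    softmax(log_odds / temperature).  temperature -> 0 makes the preference
    degenerate (argmax one-hot).
    """

    name: str
    log_odds: dict[str, np.ndarray]
    temperature: float = 1.0

    def __post_init__(self) -> None:
        labels = position_labels(5)
        if sorted(self.log_odds) != sorted(labels):
            raise ValueError("log_odds must cover exactly the 10 positions P5..P5'")
        for pos, v in self.log_odds.items():
            self.log_odds[pos] = np.asarray(v, dtype=float)
            if self.log_odds[pos].shape != (_N_RES,):
                raise ValueError(f"{pos}: expected {_N_RES} scores")

    def residue_probs(self, position: str) -> np.ndarray:
        scores = self.log_odds[position]
        if self.temperature == 0:
            if np.ptp(scores) == 0:  # no preference at this position
                return np.full(_N_RES, 1.0 / _N_RES)
            probs = np.zeros(_N_RES)
            probs[int(np.argmax(scores))] = 1.0
            return probs
        z = scores / self.temperature
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()

    def prob_matrix(self) -> np.ndarray:
        """(10, 20) matrix of per-position residue probabilities."""
        return np.stack([self.residue_probs(p) for p in position_labels(5)])

    @classmethod
    def uniform(cls, name: str) -> "SpecificityModel":
        return cls(name, {p: np.zeros(_N_RES) for p in position_labels(5)})

    @classmethod
    def with_preferences(cls, name: str,
                         preferences: dict[str, dict[str, float]],
                         temperature: float = 1.0) -> "SpecificityModel":
        """Build a model from target residue probabilities per position.

        At each listed position the named residues get the stated
        probabilities and the remainder is spread uniformly; unlisted
        positions are uniform.
        """
        log_odds = {}
        for pos in position_labels(5):
            prefs = preferences.get(pos)
            if not prefs:
                log_odds[pos] = np.zeros(_N_RES)
                continue
            total = sum(prefs.values())
            if total > 1.0 + 1e-9:
                raise ValueError(f"{pos}: preference probabilities sum to {total} > 1")
            rest = (1.0 - total) / (_N_RES - len(prefs))
            probs = np.full(_N_RES, rest)
            for res, p in prefs.items():
                probs[_RES_INDEX[res]] = p
            log_odds[pos] = np.log(np.maximum(probs, 1e-300))
        return cls(name, log_odds, temperature)


@dataclass
class ProteaseSpec:
    """One protease in the roster: specificity + rates + abundance effect."""

    model: SpecificityModel
    site_rate: float  # per eligible site planting rate (likelihood-ratio thinned)
    occurrence: dict[str, float]  # group -> per-sample occurrence probability
    log2_effect: float = 0.0  # added to case-group log2 intensity of its termini

    @property
    def name(self) -> str:
        return self.model.name


@dataclass
class CleavageEventTruth:
    accession: str
    p1_position: int
    protease: str
    occurrence: dict[str, float]
    log2_effect: float = 0.0

    def __post_init__(self) -> None:
        for g, p in self.occurrence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"occurrence[{g}]={p} outside [0, 1]")


def default_proteases(case: str = "CASE", control: str = "CTRL"
                      ) -> list[ProteaseSpec]:
    """The study-condition roster: one shared protease, one case-exclusive
    protease with a distinct P1' preference, one shared protease whose
    termini are depleted in the case group."""
    shared = SpecificityModel.with_preferences(
        "GELATINASE_SYN", {"P1'": {"G": 0.5, "S": 0.3}, "P1": {"G": 0.3, "S": 0.3}})
    case_excl = SpecificityModel.with_preferences(
        "CASEPROT_SYN", {"P1'": {"A": 0.8}})
    depleted = SpecificityModel.with_preferences(
        "CTRLPROT_SYN", {"P1'": {"V": 0.6}, "P2'": {"L": 0.4}})
    return [
        ProteaseSpec(shared, 0.008, {case: 0.7, control: 0.7}, 0.0),
        ProteaseSpec(case_excl, 0.008, {case: 0.7, control: 0.0}, 0.0),
        ProteaseSpec(depleted, 0.008, {case: 0.6, control: 0.6}, -2.0),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort (seed is mandatory)."""

    seed: int
    n_proteins: int = 100
    length_range: tuple[int, int] = (120, 500)
    signal_fraction: float = 0.5
    signal_end_range: tuple[int, int] = (15, 30)
    proteases: list[ProteaseSpec] = field(default_factory=default_proteases)
    missed_cleavage_prob: float = 0.3
    max_missed_cleavages: int = 2
    peptide_length_range: tuple[int, int] = (7, 50)
    proline_rule: bool = True
    # log2 intensity model
    mu_mean: float = 20.0
    mu_sd: float = 2.0
    noise_sd: float = 0.5
    protein_effect_fraction: float = 0.05
    protein_effect_size: float = 2.0
    terminus_mu_mean: float = 18.0
    # missingness: P(missing) = sigmoid(intercept + slope * log2 intensity)
    missing_intercept: float = 10.6
    missing_slope: float = -0.6
    # decoys: target fraction of semi-tryptic rows that are spurious
    decoy_rate: float = 0.02
    decoy_presence: float = 0.25
    site_margin: int = 10  # planted P1 kept this far from protein ends

    def __post_init__(self) -> None:
        if self.length_range[1] < self.length_range[0]:
            raise ValueError("degenerate length distribution (max < min)")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("signal_fraction", "missed_cleavage_prob", "decoy_rate",
                     "decoy_presence", "protein_effect_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for spec in self.proteases:
            if not (0.0 <= spec.site_rate <= 1.0):
                raise ValueError(f"{spec.name}: site_rate outside [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


_STREAM_PROTEOME, _STREAM_PLANT, _STREAM_REPORT = 0, 1, 2


def make_design(n_per_group: int = 8, case: str = "CASE", control: str = "CTRL"
                ) -> SampleDesign:
    samples = [f"{case}_{i + 1}" for i in range(n_per_group)] + \
              [f"{control}_{i + 1}" for i in range(n_per_group)]
    groups = {s: (case if s.startswith(case) else control) for s in samples}
    return SampleDesign(samples, groups)


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_proteome(config: SimulationConfig
                      ) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Random proteome with uniform residue composition, 'M' initiators and
    a ``signal_fraction`` of proteins carrying signal-peptide annotations."""
    rng = config.rng(_STREAM_PROTEOME)
    lo, hi = config.length_range
    records, signal_ends = [], {}
    for i in range(config.n_proteins):
        acc = f"SYN{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        body = rng.integers(0, _N_RES, size=length - 1)
        seq = "M" + "".join(AMINO_ACIDS[c] for c in body)
        signal_end = None
        if rng.random() < config.signal_fraction:
            signal_end = int(rng.integers(config.signal_end_range[0],
                                          config.signal_end_range[1] + 1))
            signal_ends[acc] = signal_end
        records.append(ProteinRecord(acc, seq, signal_end,
                                     description=f"synthetic protein {i + 1}"))
    return records, signal_ends


def _encode(seq: str) -> np.ndarray:
    return np.array([_RES_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def plant_cleavages(proteome: list[ProteinRecord], config: SimulationConfig
                    ) -> list[CleavageEventTruth]:
    """Plant endogenous cleavage sites by likelihood-ratio thinning.

    A candidate P1 is any interior position (margin residues from either
    end) whose residue is not K/R — a cleavage after K/R would be
    indistinguishable from trypsin.  Each protease accepts a candidate with
    probability ``site_rate * prod_pos 20 * p_model(residue)`` (clipped to
    1), so accepted windows follow the model's residue distribution.
    """
    if not config.proteases:
        raise ValueError("at least one protease required")
    rng = config.rng(_STREAM_PLANT)
    truths: list[CleavageEventTruth] = []
    half = 5
    for protein in proteome:
        codes = _encode(protein.sequence)
        n = len(codes)
        p1s = np.arange(config.site_margin, n - config.site_margin + 1)
        if p1s.size == 0:
            continue
        # P1 must be non-K/R (else indistinguishable from trypsin) and must
        # not coincide with the signal-peptide junction (a cleavage there is
        # by definition the mature terminus, not a neo terminus)
        keep = [protein.sequence[p - 1] not in "KR" and p != protein.signal_end
                for p in p1s]
        p1s = p1s[np.array(keep)]
        if p1s.size == 0:
            continue
        # windows: residues p1-4 .. p1+5 (1-based) = codes[p1-5 : p1+5]
        win = np.stack([codes[p - half:p + half] for p in p1s])
        taken: set[int] = set()
        for spec in config.proteases:
            probs = spec.model.prob_matrix()  # (10, 20)
            with np.errstate(divide="ignore"):
                lr = np.prod(_N_RES * probs[np.arange(2 * half), win], axis=1)
            accept = rng.random(p1s.size) < np.clip(spec.site_rate * lr, 0.0, 1.0)
            for p1 in p1s[accept]:
                if int(p1) in taken:
                    continue
                taken.add(int(p1))
                truths.append(CleavageEventTruth(
                    protein.accession, int(p1), spec.name,
                    dict(spec.occurrence), spec.log2_effect))
    return truths


def _semi_fragments(protein: ProteinRecord, p1: int, config: SimulationConfig
                    ) -> list[tuple[int, int, str]]:
    """(start, end, side) fragments pairing the endogenous boundary at P1
    with the nearest tryptic boundary, allowing missed cleavages to reach
    the identifiable length window."""
    cuts = cleavage_positions(protein.sequence, config.proline_rule)
    lo, hi = config.peptide_length_range
    out = []
    after = [c for c in cuts if c > p1] + [len(protein)]
    for c in after[: config.max_missed_cleavages + 1]:
        if lo <= c - p1 <= hi:
            out.append((p1 + 1, c, "neoN"))
            break
    before = [0] + [c for c in cuts if c < p1]
    for c in reversed(before[-(config.max_missed_cleavages + 1):]):
        if lo <= p1 - c <= hi:
            out.append((c + 1, p1, "neoC"))
            break
    return out


def simulate_peptide_report(proteome: list[ProteinRecord],
                            truths: list[CleavageEventTruth],
                            design: SampleDesign,
                            config: SimulationConfig
                            ) -> tuple[list[PeptideReportRow], pd.DataFrame, pd.DataFrame]:
    """Emit the peptide observation table plus truth sidecars.

    Returns (rows, row_sidecar, site_table).  The sidecar has one record per
    emitted row with its provenance (``tryptic``, ``truth:<protease>`` or
    ``decoy``); the site table records, for every planted site, whether any
    semi-tryptic evidence row was emitted.
    """
    rng = config.rng(_STREAM_REPORT)
    case = design.groups[0]
    samples = design.samples
    group_of = design.group_of
    by_acc = {p.accession: p for p in proteome}

    affected = {p.accession: 0.0 for p in proteome}
    for p in proteome:
        if rng.random() < config.protein_effect_fraction:
            affected[p.accession] = config.protein_effect_size * (
                1.0 if rng.random() < 0.5 else -1.0)

    def missing_mask(values: np.ndarray) -> np.ndarray:
        z = config.missing_intercept + config.missing_slope * values
        p_miss = 1.0 / (1.0 + np.exp(-z))
        return rng.random(values.size) < p_miss

    rows: list[PeptideReportRow] = []
    sidecar: list[dict] = []

    def emit(peptide: str, protein: ProteinRecord, start: int, end: int,
             values: np.ndarray, present: np.ndarray, provenance: str,
             p1: int | None, fdr: float) -> None:
        mask = missing_mask(values) | ~present
        intensities = {
            s: (math.nan if mask[i] else float(2.0 ** values[i]))
            for i, s in enumerate(samples)}
        rows.append(PeptideReportRow(
            peptide=peptide, proteins=(protein.accession,),
            start=start, end=end,
            prev_aa=protein.residue(start - 1), next_aa=protein.residue(end + 1),
            intensities=intensities, fdr=fdr))
        sidecar.append({"row_id": len(rows) - 1, "provenance": provenance,
                        "accession": protein.accession, "start": start,
                        "end": end, "p1_position": -1 if p1 is None else p1})

    # --- fully tryptic background ---------------------------------------
    for protein in proteome:
        locs = digest_protein(protein.sequence, config.max_missed_cleavages,
                              config.peptide_length_range, config.proline_rule,
                              protein.accession)
        cutset = set(cleavage_positions(protein.sequence, config.proline_rule))
        for loc in locs:
            mc = sum(1 for c in cutset if loc.start <= c < loc.end)
            if mc > 0 and rng.random() >= config.missed_cleavage_prob ** mc:
                continue
            mu = rng.normal(config.mu_mean, config.mu_sd)
            effect = affected[protein.accession]
            values = np.array([
                mu + (effect if group_of[s] == case else 0.0)
                + rng.normal(0.0, config.noise_sd)
                for s in samples])
            fdr = float(rng.uniform(0.0, 0.008)) if rng.random() < 0.98 \
                else float(rng.uniform(0.011, 0.05))
            emit(protein.sequence[loc.start - 1:loc.end], protein,
                 loc.start, loc.end, values,
                 np.ones(len(samples), dtype=bool), "tryptic", None, fdr)

    # --- endogenous (truth) semi-tryptic evidence ------------------------
    site_records = []
    n_truth_semi = 0
    for truth in truths:
        protein = by_acc[truth.accession]
        frags = _semi_fragments(protein, truth.p1_position, config)
        emitted_sides: set[str] = set()
        for start, end, side in frags:
            mu = rng.normal(config.terminus_mu_mean, config.mu_sd)
            present = np.array([
                rng.random() < truth.occurrence[group_of[s]] for s in samples])
            values = np.array([
                mu + (truth.log2_effect if group_of[s] == case else 0.0)
                + rng.normal(0.0, config.noise_sd)
                for s in samples])
            emit(protein.sequence[start - 1:end], protein, start, end,
                 values, present, f"truth:{truth.protease}",
                 truth.p1_position, float(rng.uniform(0.0, 0.008)))
            emitted_sides.add(side)
            n_truth_semi += 1
        site_records.append({
            "accession": truth.accession, "p1_position": truth.p1_position,
            "protease": truth.protease, "log2_effect": truth.log2_effect,
            "emitted": bool(emitted_sides),
            "emitted_neoN": "neoN" in emitted_sides,
            "emitted_neoC": "neoC" in emitted_sides,
            **{f"occurrence_{g}": truth.occurrence[g] for g in design.groups}})

    # --- decoy semi-tryptic noise ----------------------------------------
    if config.decoy_rate > 0 and n_truth_semi > 0:
        odds = config.decoy_rate / (1.0 - config.decoy_rate)
        n_decoys = int(rng.binomial(n_truth_semi, min(odds, 1.0)))
        truth_p1s = {(t.accession, t.p1_position) for t in truths}
        attempts = 0
        planted = 0
        while planted < n_decoys and attempts < 50 * max(n_decoys, 1):
            attempts += 1
            protein = proteome[int(rng.integers(0, len(proteome)))]
            if len(protein) <= 2 * config.site_margin:
                continue
            p1 = int(rng.integers(config.site_margin,
                                  len(protein) - config.site_margin + 1))
            if protein.sequence[p1 - 1] in "KR":
                continue
            if (protein.accession, p1) in truth_p1s:
                continue
            frags = _semi_fragments(protein, p1, config)
            frags = [f for f in frags if f[2] == "neoN"]
            if not frags:
                continue
            start, end, _ = frags[0]
            mu = rng.normal(config.terminus_mu_mean, config.mu_sd)
            present = rng.random(len(samples)) < config.decoy_presence
            if not present.any():
                continue
            values = mu + rng.normal(0.0, config.noise_sd, size=len(samples))
            emit(protein.sequence[start - 1:end], protein, start, end,
                 values, present, "decoy", p1, float(rng.uniform(0.0, 0.008)))
            planted += 1

    return rows, pd.DataFrame(sidecar), pd.DataFrame(site_records)


@dataclass
class SimulationResult:
    config: SimulationConfig
    design: SampleDesign
    proteome: list[ProteinRecord]
    signal_ends: dict[str, int]
    truths: list[CleavageEventTruth]
    rows: list[PeptideReportRow]
    row_sidecar: pd.DataFrame
    site_table: pd.DataFrame


def simulate_cohort(config: SimulationConfig,
                    design: SampleDesign | None = None) -> SimulationResult:
    design = design or make_design()
    proteome, signal_ends = generate_proteome(config)
    truths = plant_cleavages(proteome, config)
    rows, sidecar, sites = simulate_peptide_report(proteome, truths, design, config)
    return SimulationResult(config, design, proteome, signal_ends, truths,
                            rows, sidecar, sites)


def write_simulation(result: SimulationResult, outdir) -> dict[str, str]:
    """Write proteome.fasta, signal_peptides.tsv, peptides.tsv, design.tsv,
    truth_sites.tsv and truth_rows.tsv under ``outdir``."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "signal": outdir / "signal_peptides.tsv",
        "peptides": outdir / "peptides.tsv",
        "design": outdir / "design.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_rows": outdir / "truth_rows.tsv",
    }
    write_fasta(result.proteome, paths["fasta"])
    write_signal_table(result.signal_ends, paths["signal"])
    write_peptide_report(result.rows, paths["peptides"], result.design.samples)
    write_design(result.design, paths["design"])
    result.site_table.to_csv(paths["truth_sites"], sep="\t", index=False)
    result.row_sidecar.to_csv(paths["truth_rows"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
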