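"""End-to-end orchestration: simulate (optional) -> master-protein filter ->
normalize/impute -> protein differential abundance -> terminus calling ->
terminus differential abundance -> cleavage profiling -> protease
enrichment, with one run report.

Stage order is fixed (protein level first, terminome second) so reports are
comparable across runs; all randomness flows from the master seed through
named substreams, making stage-level reruns reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cleavage_profile import (build_pfm, compare_group_preferences,
                               enrichment_to_frame, match_known_sites,
                               protease_enrichment, windows_for_events)
from .diffstats import differential_analysis, impute_cart, pca_variance, \
    quantile_normalize_by_class
from .digestion import resolve_location
from .io_formats import (CleavageSiteRecord, PeptideReportRow, PipelineConfig,
                         ProteinRecord, SampleDesign, read_cleavage_db,
                         read_design, read_fasta, read_peptide_report,
                         read_signal_table, write_json)
from .terminome import (NEO, TerminusEvent, call_termini, events_from_frame,
                        events_intensity_matrix, events_to_frame, events_venn,
                        exclusivity_label, filter_master_proteins,
                        partition_venn, presence_filter)

logger = logging.getLogger("terminome_miner")

#: substream indices for the master seed
SEED_IMPUTE_PROTEIN, SEED_IMPUTE_TERMINUS = 10, 11


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# protein level
# ---------------------------------------------------------------------------

def build_protein_table(rows: list[PeptideReportRow],
                        proteome: dict[str, ProteinRecord]) -> pd.DataFrame:
    """Per-protein unique-peptide counts and identification FDR (best peptide)."""
    uniques: dict[str, set[str]] = {}
    fdrs: dict[str, float] = {}
    for row in rows:
        loc = resolve_location(row.proteins, row.peptide, row.start, row.end, proteome)
        if loc is None or not loc.unique:
            continue
        uniques.setdefault(loc.accession, set()).add(row.peptide)
        fdrs[loc.accession] = min(fdrs.get(loc.accession, 1.0), row.fdr)
    return pd.DataFrame({
        "accession": sorted(uniques),
        "unique_peptides": [len(uniques[a]) for a in sorted(uniques)],
        "fdr": [fdrs[a] for a in sorted(uniques)],
    })


def build_protein_matrix(rows: list[PeptideReportRow],
                         proteome: dict[str, ProteinRecord],
                         design: SampleDesign,
                         accessions: set[str]) -> pd.DataFrame:
    """Raw protein intensities: per-sample sum over unique peptide rows."""
    data: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    ns = len(design.samples)
    for row in rows:
        loc = resolve_location(row.proteins, row.peptide, row.start, row.end, proteome)
        if loc is None or not loc.unique or loc.accession not in accessions:
            continue
        acc = loc.accession
        if acc not in data:
            data[acc] = np.zeros(ns)
            counts[acc] = np.zeros(ns, dtype=int)
        for i, s in enumerate(design.samples):
            v = row.intensities.get(s, math.nan)
            if v is not None and not math.isnan(v):
                data[acc][i] += v
                counts[acc][i] += 1
    index = sorted(data)
    mat = np.full((len(index), ns), math.nan)
    for r, acc in enumerate(index):
        obs = counts[acc] > 0
        mat[r, obs] = data[acc][obs]
    return pd.DataFrame(mat, index=index, columns=design.samples)


def prepare_matrix(raw: pd.DataFrame, design: SampleDesign,
                   config: PipelineConfig, impute_seed: int) -> pd.DataFrame:
    """log2-transform, class-specific quantile normalization, CART imputation."""
    log2 = np.log2(raw.where(raw > 0))
    norm = quantile_normalize_by_class(log2, design)
    return impute_cart(norm, seed=impute_seed)


# ---------------------------------------------------------------------------
# enrichment foreground selection
# ---------------------------------------------------------------------------

def enrichment_foreground(events: list[TerminusEvent], dea: pd.DataFrame,
                          design: SampleDesign, group: str,
                          config: PipelineConfig) -> list[TerminusEvent]:
    """The study submits, per group, that group's exclusive termini plus its
    significantly changed termini (up for the case group, down for the
    other, with case = first group of the differential contrast)."""
    case = dea.attrs.get("case_group", design.groups[0])
    want_status = "up" if group == case else "down"
    by_id = {f"{e.accession}:{e.terminus_type}{e.p1_position}": e for e in events}
    chosen: dict = {}
    for ev in events:
        if exclusivity_label(ev, design, config.exclusivity_fraction) == f"exclusive_{group}":
            chosen[ev.key] = ev
    if "status" in dea.columns:
        for fid in dea.index[dea["status"] == want_status]:
            ev = by_id.get(str(fid))
            if ev is not None:
                chosen[ev.key] = ev
    return list(chosen.values())


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config: dict
    seed: int
    version: str = __version__
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"version": self.version, "seed": self.seed,
                "config": self.config, "counts": self.counts,
                "warnings": self.warnings}


def run_all(config: PipelineConfig, input_dir: str | Path, out_dir: str | Path,
            sim_config=None) -> RunReport:
    """Execute the full analysis.

    ``input_dir`` must contain proteome.fasta, signal_peptides.tsv,
    peptides.tsv, design.tsv (and optionally cleavage_db.tsv plus the truth
    sidecars when the cohort was simulated).  If ``sim_config`` is given the
    cohort is simulated into ``input_dir`` first.  All stage outputs are
    written under ``out_dir``; any stage failure writes a FAILED sentinel
    and raises :class:`StageError`.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), seed=config.seed)
    stage = "setup"
    try:
        if sim_config is not None:
            stage = "simulate"
            from .synthetic_data import simulate_cohort, write_simulation
            result = simulate_cohort(sim_config)
            write_simulation(result, input_dir)

        stage = "load"
        signal_ends = read_signal_table(input_dir / "signal_peptides.tsv")
        proteome_list = read_fasta(input_dir / "proteome.fasta", signal_ends)
        proteome = {p.accession: p for p in proteome_list}
        design = read_design(input_dir / "design.tsv")
        rows = read_peptide_report(input_dir / "peptides.tsv", config.dialect,
                                   config.zero_is_missing)
        db_path = input_dir / "cleavage_db.tsv"
        cleavage_db: list[CleavageSiteRecord] = (
            read_cleavage_db(db_path) if db_path.exists() else [])

        # ---- protein level ------------------------------------------------
        stage = "protein_filter"
        table = build_protein_table(rows, proteome)
        master = filter_master_proteins(table, config)
        master.to_csv(out_dir / "protein_table.tsv", sep="\t", index=False)
        report.counts["proteins_identified"] = int(len(table))
        report.counts["proteins_master"] = int(len(master))

        stage = "protein_matrix"
        raw = build_protein_matrix(rows, proteome, design,
                                   set(master["accession"]))
        raw.to_csv(out_dir / "protein_matrix_raw.tsv", sep="\t",
                   index_label="feature")
        a, b = design.groups
        present_a = set(raw.index[raw[design.members(a)].notna().any(axis=1)])
        present_b = set(raw.index[raw[design.members(b)].notna().any(axis=1)])
        venn_prot = partition_venn(present_a, present_b, a, b)
        report.counts["protein_venn"] = venn_prot.sizes

        stage = "protein_dea"
        norm = prepare_matrix(raw, design, config,
                              np.random.SeedSequence([config.seed, SEED_IMPUTE_PROTEIN])
                              .generate_state(1)[0] % (2 ** 31))
        norm.to_csv(out_dir / "protein_matrix_norm.tsv", sep="\t",
                    index_label="feature")
        dea_prot = differential_analysis(norm, design, config, mode="protein")
        dea_prot.to_csv(out_dir / "dea_proteins.tsv", sep="\t",
                        index_label="feature")
        pca = pca_variance(norm)
        write_json({"variance_fraction": [float(v) for v in pca],
                    "top3_fraction": float(pca[:3].sum())},
                   out_dir / "pca_summary.json")
        report.counts["deps"] = {
            "up": int((dea_prot["status"] == "up").sum()),
            "down": int((dea_prot["status"] == "down").sum()),
            "total": int((dea_prot["status"] != "ns").sum()),
        }

        # ---- terminome ----------------------------------------------------
        stage = "call_termini"
        n_events, c_events, counters = call_termini(rows, proteome, design, config)
        n_kept = presence_filter(n_events, design, config.min_presence)
        c_kept = presence_filter(c_events, design, config.min_presence)
        events_to_frame(n_kept, design, config).to_csv(
            out_dir / "n_termini.tsv", sep="\t", index=False)
        events_to_frame(c_kept, design, config).to_csv(
            out_dir / "c_termini.tsv", sep="\t", index=False)
        venn_n = events_venn(n_kept, design)
        venn_c = events_venn(c_kept, design)
        write_json({"proteins": venn_prot.sizes, "n_termini": venn_n.sizes,
                    "c_termini": venn_c.sizes}, out_dir / "venn_summary.json")
        report.counts["n_termini"] = venn_n.sizes
        report.counts["c_termini"] = venn_c.sizes
        report.counts["n_termini_category"] = {
            cat: sum(1 for e in n_kept if e.category == cat)
            for cat in ("mature", "neo")}
        report.counts["terminus_call"] = counters

        stage = "terminus_dea"
        dea_term = pd.DataFrame()
        if len(n_kept) >= 2:
            term_raw = events_intensity_matrix(n_kept, design)
            term_norm = prepare_matrix(
                term_raw, design, config,
                np.random.SeedSequence([config.seed, SEED_IMPUTE_TERMINUS])
                .generate_state(1)[0] % (2 ** 31))
            dea_term = differential_analysis(term_norm, design, config,
                                             mode="terminus")
            dea_term.to_csv(out_dir / "dea_termini.tsv", sep="\t",
                            index_label="feature")
            report.counts["termini_diff"] = {
                "up": int((dea_term["status"] == "up").sum()),
                "down": int((dea_term["status"] == "down").sum()),
            }
        else:
            report.warnings.append("too few N-termini for differential testing")
            report.counts["termini_diff"] = {"up": 0, "down": 0}

        # ---- cleavage profiling -------------------------------------------
        stage = "cleavage_profile"
        pfms = {}
        for group in design.groups:
            members = design.members(group)
            group_events = [e for e in n_kept
                            if e.presence_count(members) > 0 and e.category == NEO]
            windows = windows_for_events(group_events, proteome,
                                         config.window_half_width)
            if windows:
                pfm = build_pfm(windows, config.window_half_width)
                pfms[group] = pfm
                pfm.frequencies.to_csv(out_dir / f"pfm_{group}.tsv", sep="\t",
                                       index_label="position")
                pfm.to_logo_frame().to_csv(out_dir / f"logo_data_{group}.tsv",
                                           sep="\t", index=False)
        if len(pfms) == 2:
            ga, gb = design.groups
            compare_group_preferences(pfms[ga], pfms[gb]).to_csv(
                out_dir / "pfm_log_ratios.tsv", sep="\t", index_label="position")

        stage = "protease_enrichment"
        if cleavage_db and n_kept:
            ann = match_known_sites(n_kept, cleavage_db)
            pd.DataFrame(
                [{"accession": k[0], "terminus_type": k[1], "p1_position": k[2],
                  "proteases": ";".join(v)} for k, v in sorted(ann.items())]
            ).to_csv(out_dir / "annotations.tsv", sep="\t", index=False)
            frames = []
            for group in design.groups:
                fore = enrichment_foreground(n_kept, dea_term, design, group, config)
                if not fore:
                    continue
                res = protease_enrichment(fore, n_kept, cleavage_db)
                frame = enrichment_to_frame(res)
                frame.insert(0, "group", group)
                frames.append(frame)
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    out_dir / "protease_enrichment.tsv", sep="\t", index=False)

        stage = "report"
        truth_path = input_dir / "truth_sites.tsv"
        if truth_path.exists():
            sites = pd.read_csv(truth_path, sep="\t")
            emitted = sites[sites["emitted_neoN"]]
            truth_set = set(zip(emitted["accession"], emitted["p1_position"]))
            called = {(e.accession, e.p1_position) for e in n_events
                      if e.category == NEO}
            tp = len(truth_set & called)
            report.counts["truth_recovery"] = {
                "recall": tp / len(truth_set) if truth_set else float("nan"),
                "precision": tp / len(called) if called else float("nan"),
                "n_truth": len(truth_set), "n_called": len(called),
            }
        write_json(report.to_dict(), out_dir / "run_report.json")
    except Exception as exc:  # noqa: BLE001 - stage-named abort contract
        (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc
    return report
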