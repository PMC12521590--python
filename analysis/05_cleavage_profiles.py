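#!/usr/bin/env python
"""Cleavage-site specificity profiling: P5..P5' windows of every neo
N-terminus, per-group position frequency matrices (sequence-logo tables)
and the case/control log-ratio of residue preferences.

Reads results/cohort/ and results/terminome/, writes results/cleavage/.
"""

import argparse
from pathlib import Path

import pandas as pd

from terminome_miner.cleavage_profile import (build_pfm,
                                              compare_group_preferences,
                                              windows_for_events)
from terminome_miner.io_formats import PipelineConfig, read_design, read_fasta
from terminome_miner.terminome import events_from_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    args = parser.parse_args()

    cohort = ROOT / "results" / "cohort"
    outdir = ROOT / "results" / "cleavage"
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig()

    proteome = {p.accession: p for p in read_fasta(cohort / "proteome.fasta")}
    design = read_design(cohort / "design.tsv")
    events = events_from_frame(
        pd.read_csv(ROOT / "results" / "terminome" / "n_termini.tsv", sep="\t"),
        design)

    pfms = {}
    for group in design.groups:
        members = design.members(group)
        grp = [e for e in events
               if e.presence_count(members) > 0 and e.category == "neo"]
        windows = windows_for_events(grp, proteome, config.window_half_width)
        pfm = build_pfm(windows, config.window_half_width)
        pfms[group] = pfm
        pfm.frequencies.to_csv(outdir / f"pfm_{group}.tsv", sep="\t",
                               index_label="position")
        pfm.to_logo_frame().to_csv(outdir / f"logo_data_{group}.tsv",
                                   sep="\t", index=False)
        top = pfm.top_residues()
        p1_prime = "P1'"
        print(f"{group}: {pfm.n_windows} windows; "
              f"P1 top {top['P1']} ({pfm.frequencies.loc['P1'].max():.2f}), "
              f"P1' top {top[p1_prime]} "
              f"({pfm.frequencies.loc[p1_prime].max():.2f})")

    a, b = design.groups
    ratios = compare_group_preferences(pfms[a], pfms[b])
    ratios.to_csv(outdir / "pfm_log_ratios.tsv", sep="\t", index_label="position")
    p1p = ratios.loc["P1'"]
    print(f"largest {a}/{b} P1' preference shift: "
          f"{p1p.idxmax()} ({p1p.max():+.2f} log2)")


if __name__ == "__main__":
    main()
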