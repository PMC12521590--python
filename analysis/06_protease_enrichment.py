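#!/usr/bin/env python
"""Protease attribution and enrichment: called termini are matched exactly
against a cleavage-site database (here, the simulation's own planted sites
standing in for a curated degradomics resource) and each protease is tested
for over-representation among the case-exclusive termini.

Reads results/cohort/ and results/terminome/, writes results/cleavage/.
"""

import argparse
from pathlib import Path

import pandas as pd

from terminome_miner.cleavage_profile import (enrichment_to_frame,
                                              match_known_sites,
                                              protease_enrichment)
from terminome_miner.io_formats import (CleavageSiteRecord, PipelineConfig,
                                        read_design)
from terminome_miner.terminome import events_from_frame, exclusivity_label

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    args = parser.parse_args()

    cohort = ROOT / "results" / "cohort"
    outdir = ROOT / "results" / "cleavage"
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig()

    design = read_design(cohort / "design.tsv")
    events = events_from_frame(
        pd.read_csv(ROOT / "results" / "terminome" / "n_termini.tsv", sep="\t"),
        design)
    events = [e for e in events if e.category == "neo"]
    sites = pd.read_csv(cohort / "truth_sites.tsv", sep="\t")
    db = [CleavageSiteRecord(r.accession, int(r.p1_position), r.protease)
          for r in sites.itertuples()]

    annotations = match_known_sites(events, db)
    n_known = sum(1 for v in annotations.values() if v != ["novel"])
    print(f"{n_known}/{len(events)} neo N-termini match a database cleavage site")

    frames = []
    for group in design.groups:
        fore = [e for e in events
                if exclusivity_label(e, design, config.exclusivity_fraction)
                == f"exclusive_{group}"]
        if not fore:
            print(f"{group}: no exclusive termini, enrichment skipped")
            continue
        frame = enrichment_to_frame(protease_enrichment(fore, events, db))
        frame.insert(0, "group", group)
        frames.append(frame)
        sig = frame[frame["q_bh"] <= config.alpha_q]
        label = ", ".join(f"{r.protease} (q={r.q_bh:.2g})"
                          for r in sig.itertuples()) or "none at q <= 0.05"
        print(f"{group}: {len(fore)} exclusive termini; enriched proteases: {label}")
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "protease_enrichment.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
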