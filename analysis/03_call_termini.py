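#!/usr/bin/env python
"""Mine endogenous N- and C-termini from the cohort peptide report: non-K/R
flanking-residue calls, mature/neo classification, the 3-of-8 presence
filter, group Venn partitions and truth-recovery scoring.

Reads results/cohort/, writes results/terminome/.
"""

import argparse
from pathlib import Path

import pandas as pd

from terminome_miner.io_formats import (PipelineConfig, read_design,
                                        read_fasta, read_peptide_report,
                                        read_signal_table, write_json)
from terminome_miner.terminome import (call_termini, events_to_frame,
                                       events_venn, presence_filter)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    cohort = ROOT / "results" / "cohort"
    outdir = ROOT / "results" / "terminome"
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(seed=args.seed)

    signal_ends = read_signal_table(cohort / "signal_peptides.tsv")
    proteome = {p.accession: p
                for p in read_fasta(cohort / "proteome.fasta", signal_ends)}
    design = read_design(cohort / "design.tsv")
    rows = read_peptide_report(cohort / "peptides.tsv")

    n_events, c_events, counters = call_termini(rows, proteome, design, config)
    n_kept = presence_filter(n_events, design, config.min_presence)
    c_kept = presence_filter(c_events, design, config.min_presence)
    events_to_frame(n_kept, design, config).to_csv(outdir / "n_termini.tsv",
                                                   sep="\t", index=False)
    events_to_frame(c_kept, design, config).to_csv(outdir / "c_termini.tsv",
                                                   sep="\t", index=False)
    venn_n, venn_c = events_venn(n_kept, design), events_venn(c_kept, design)
    write_json({"n_termini": venn_n.sizes, "c_termini": venn_c.sizes,
                "counters": counters}, outdir / "venn_summary.json")

    sites = pd.read_csv(cohort / "truth_sites.tsv", sep="\t")
    truth = set(zip(sites[sites.emitted_neoN].accession,
                    sites[sites.emitted_neoN].p1_position))
    called = {(e.accession, e.p1_position) for e in n_events
              if e.category == "neo"}
    tp = len(truth & called)
    print(f"N-termini after presence filter: {len(n_kept)} "
          f"({sum(e.category == 'mature' for e in n_kept)} mature, "
          f"{sum(e.category == 'neo' for e in n_kept)} neo); Venn {venn_n.sizes}")
    print(f"C-termini: {len(c_kept)}; Venn {venn_c.sizes}")
    print(f"neo-N truth recovery: recall {tp / len(truth):.3f}, "
          f"precision {tp / len(called):.3f}")


if __name__ == "__main__":
    main()
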