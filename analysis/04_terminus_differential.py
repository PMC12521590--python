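#!/usr/bin/env python
"""Terminus-level differential abundance: the N-terminus intensity matrix is
normalized and imputed independently of the protein matrix and tested with
the moderated t; significance here uses p_mod only (q-values at the
terminus level rarely reach the protein-level stringency).

Reads results/cohort/ and results/terminome/, writes results/terminome/.
"""

import argparse
from pathlib import Path

from terminome_miner.diffstats import differential_analysis
from terminome_miner.io_formats import (PipelineConfig, read_design,
                                        read_fasta, read_peptide_report,
                                        read_signal_table)
from terminome_miner.pipeline import prepare_matrix
from terminome_miner.terminome import (call_termini, events_intensity_matrix,
                                       presence_filter)

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

    n_events, _, _ = call_termini(rows, proteome, design, config)
    n_kept = presence_filter(n_events, design, config.min_presence)
    raw = events_intensity_matrix(n_kept, design)
    norm = prepare_matrix(raw, design, config, config.seed + 1)
    dea = differential_analysis(norm, design, config, mode="terminus")
    dea.to_csv(outdir / "dea_termini.tsv", sep="\t", index_label="feature")

    up, down = (dea["status"] == "up").sum(), (dea["status"] == "down").sum()
    print(f"{len(dea)} termini tested: {up} up, {down} down in "
          f"{dea.attrs['case_group']} (p_mod <= {config.alpha_p}, "
          f"|log2FC| >= {config.lfc_threshold})")


if __name__ == "__main__":
    main()
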