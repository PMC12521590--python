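#!/usr/bin/env python
"""Protein-level analysis of the simulated cohort: master-protein filter,
presence Venn, class-specific quantile normalization, CART imputation,
moderated t with Storey q, DEP calls and PCA variance summary.

Reads results/cohort/, writes results/protein/.
"""

import argparse
from pathlib import Path

from terminome_miner.diffstats import differential_analysis, pca_variance
from terminome_miner.io_formats import (PipelineConfig, read_design,
                                        read_fasta, read_peptide_report,
                                        read_signal_table, write_json)
from terminome_miner.pipeline import (build_protein_matrix,
                                      build_protein_table, prepare_matrix)
from terminome_miner.terminome import filter_master_proteins, partition_venn

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    cohort = ROOT / "results" / "cohort"
    outdir = ROOT / "results" / "protein"
    outdir.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(seed=args.seed)

    signal_ends = read_signal_table(cohort / "signal_peptides.tsv")
    proteome = {p.accession: p
                for p in read_fasta(cohort / "proteome.fasta", signal_ends)}
    design = read_design(cohort / "design.tsv")
    rows = read_peptide_report(cohort / "peptides.tsv")

    table = build_protein_table(rows, proteome)
    master = filter_master_proteins(table, config)
    master.to_csv(outdir / "protein_table.tsv", sep="\t", index=False)

    raw = build_protein_matrix(rows, proteome, design, set(master["accession"]))
    a, b = design.groups
    venn = partition_venn(
        set(raw.index[raw[design.members(a)].notna().any(axis=1)]),
        set(raw.index[raw[design.members(b)].notna().any(axis=1)]), a, b)

    norm = prepare_matrix(raw, design, config, config.seed)
    dea = differential_analysis(norm, design, config, mode="protein")
    dea.to_csv(outdir / "dea_proteins.tsv", sep="\t", index_label="feature")
    pca = pca_variance(norm)
    write_json({"variance_fraction": [float(v) for v in pca],
                "top3_fraction": float(pca[:3].sum())},
               outdir / "pca_summary.json")

    up, down = (dea["status"] == "up").sum(), (dea["status"] == "down").sum()
    print(f"{len(master)} master proteins; Venn {venn.sizes}")
    print(f"DEPs (|log2FC| >= {config.lfc_threshold}, p and q <= 0.05): "
          f"{up} up, {down} down")
    print(f"top 3 PCs explain {100 * pca[:3].sum():.1f}% of variance")


if __name__ == "__main__":
    main()
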