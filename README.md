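# terminome-miner

Degradomics analysis of label-free shotgun proteomics cohorts: protein-level
differential abundance with moderated statistics, plus mining of endogenous
protein **N- and C-termini** (the "terminome") from semi-tryptic peptides,
cleavage-site specificity profiling and protease attribution.

The package reimplements, as a tested and reusable pipeline, the analysis
used to compare the vitreous-humor (VH) proteome and degradome of
rhegmatogenous retinal detachment (RRD) patients against controls: two
groups of n = 8 subjects, Proteome Discoverer / FragPipe-style peptide
reports, and a terminus-calling strategy based on the absence of K/R at the
peptide's flanking positions. Because the raw mass-spectrometry data are
not needed for validating the statistics, the package ships a synthetic
degradome generator that plants proteolytic cleavages with known positional
specificities and group-dependent rates, so every downstream stage is
testable by recovery of the ground truth.

## The model at the core

**Terminus calling.** A peptide evidences an endogenous N-terminus when its
N-terminal flanking residue is not K/R (so sample-preparation trypsin cannot
explain the boundary). Called N-termini are *mature* when the peptide starts
at the database N-terminus (position 1/2) or at `signal_end + 1`, and *neo*
otherwise; C-termini are symmetric (last residue not K/R). Cleavage sites
are written P1↓P1′ (Schechter–Berger), with P1 the residue N-terminal to
the scissile bond.

**Differential abundance.** For feature *g* with pooled residual variance
s²_g on d_g = n₁+n₂−2 df, the empirical-Bayes moderated statistic is

    t_g = (x̄_case − x̄_ctrl) / (s̃_g √(1/n₁ + 1/n₂)),
    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),

with (d₀, s₀²) estimated by moment-matching the log sample variances
(digamma/trigamma inversion) and p-values from a t distribution on
d₀ + d_g df. FDR control uses Storey q-values with a single-λ π₀ estimate:
π₀ = min(1, #{p > λ}/(m(1−λ))). A feature is differentially expressed when
|log₂FC| ≥ 0.57 with p_mod ≤ 0.05 and q_mod ≤ 0.05 (terminus-level lists
use p_mod only). Intensities are log₂-transformed, quantile-normalized
*within each class*, and missing values are imputed by regression-tree
(CART) predictive matching before testing.

**Cleavage profiling.** Every neo terminus contributes a P5..P5′ residue
window; per-group position frequency matrices give sequence-logo tables,
and proteases from a cleavage-site database are tested for one-sided
hypergeometric enrichment among group-exclusive termini, BH-corrected.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # 2x8 subjects, 100 proteins
python analysis/02_protein_differential.py
python analysis/03_call_termini.py
python analysis/04_terminus_differential.py
python analysis/05_cleavage_profiles.py
python analysis/06_protease_enrichment.py
```

prints (seed 11):

```
  proteins: 100 (56 with signal peptides)
  planted cleavage sites: 676 (666 with neo-N evidence)
  peptide rows: {'tryptic': 2601, 'truth': 1313, 'decoy': 26}
...
N-termini after presence filter: 509 (72 mature, 437 neo); Venn {'common': 363, 'exclusive_CASE': 126, 'exclusive_CTRL': 20}
neo-N truth recovery: recall 1.000, precision 0.962
...
CASE: 418 windows; P1 top S (0.20), P1' top A (0.28)
CTRL: 311 windows; P1 top S (0.25), P1' top G (0.29)
largest CASE/CTRL P1' preference shift: A (+3.36 log2)
...
CASE: 83 exclusive termini; enriched proteases: CASEPROT_SYN (q=8.2e-56)
```

Reading: of 676 planted cleavage sites, every one with emitted neo-N
evidence is recalled and 96% of called sites are genuine (the rest are the
planted 2% decoy floor). The case-exclusive protease — planted with an
alanine preference at P1′ and active only in the CASE group — dominates
the CASE-exclusive termini and is recovered by the enrichment test, and the
recovered P1′ preference shift (A, +3.4 log₂) matches the planted
specificity contrast.

The same stages are available as one command over arbitrary inputs
(`terminome-miner run-all --input DIR --out DIR [--simulate]`), with
subcommands `simulate`, `call-termini`, `dea`, `cleavage` and `enrich`.

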