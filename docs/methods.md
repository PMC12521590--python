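# Methods

## Scope and data model

The pipeline analyses a two-group label-free proteomics cohort at two
levels: (1) protein abundance, from fully tryptic peptides, and (2) the
endogenous terminome, from semi-tryptic peptides whose non-tryptic boundary
marks a proteolytic event. All coordinates are 1-based inclusive; a
cleavage site is identified by its P1 residue index (the residue
immediately N-terminal to the scissile bond, written P1↓P1′).

Peptide reports are accepted in three dialects (`generic`, `pd`,
`fragpipe`) that differ only in column naming; blank intensity cells are
always missing and zeros are missing by default (`zero_is_missing=False`
overrides), since label-free "not observed" is not evidence of zero
abundance. Rows listing several proteins, or mapping ambiguously, are
excluded from quantification and terminus calling but counted.

## Terminus calling

A row calls an N-terminus when its N-flanking residue is not K/R; it calls
a C-terminus when its last residue is not K/R. By default the *other*
boundary must be tryptic-compatible (pure semi-tryptic evidence);
`allow_non_tryptic` relaxes this, because the two search engines the
pipeline emulates differ in whether non-tryptic peptides survive scoring.
Start positions 1 and 2 both count as the database N-terminus (position 2
covers initiator-methionine excision). N-termini are *mature* at the
database start or at `signal_end + 1`, *neo* elsewhere; C-terminal peptides
ending at the protein's last residue are the database C-terminus and are
excluded from neo statistics, by symmetry with the N side. Database-start
mature calls carry a separate audit flag.

Events from distinct peptides sharing (accession, terminus type, P1) are
merged: presence vectors OR-ed, per-sample intensities summed. Presence
means a non-missing intensity in that sample ("identified and quantified")
and is counted on raw intensities, before imputation — imputation would
fabricate presence. The default presence filter keeps events seen in ≥ 3
subjects of at least one group; exclusivity labels are computed at two
fractions (≥ 50% "exclusive", ≥ 75% "specific"), requiring zero presence
in the other group.

## Statistics

**Normalization.** Class-specific quantile normalization: within each
group independently, each sample's observed values are replaced by the
mean of the group's order statistics at the same rank. Samples with
unequal observed counts are aligned on the (r − 0.5)/n quantile scale by
linear interpolation; ties receive the average of their tied targets.
Missing cells are excluded from ranking and stay missing. A group with one
sample is left unchanged with a warning.

**Imputation.** CART predictive matching, one sweep: sample columns are
visited in order of increasing missingness; a regression tree
(`min_samples_leaf=5`, unlimited depth) predicts the column from all other
columns (mean-initialized) on its observed rows, and each missing cell
draws uniformly from the observed donors in its terminal node.
Deterministic given the seed; a single imputation is the default —
multiple-imputation pooling is out of scope. Features with no observed
value anywhere are dropped with a warning.

**Moderated test.** Hyperparameters (d₀, s₀²) are estimated by
moment-matching the log sample variances using digamma/trigamma inversion
(Newton). When the log-variance dispersion does not exceed chi-square
sampling noise, d₀ = ∞ and s₀² is the mean sample variance; the total df
is capped at the pooled residual df of the matrix. These conventions match
the reference empirical-Bayes implementation to machine precision (a test
cross-checks against it through Rscript). `prior_df=0` recovers the
ordinary pooled t exactly, which the oracle tests exploit.

**Multiple testing.** Storey q-values with fixed λ = 0.5 (single-λ π₀
rather than the spline — deterministic and robust at small feature
counts); with π₀ = 1 this reduces exactly to Benjamini–Hochberg.
Protein-level calls require p_mod ≤ 0.05 *and* q_mod ≤ 0.05 with
|log₂FC| ≥ 0.57, all inclusive; terminus-level calls use p_mod only,
mirroring how terminus-level q-values rarely reach protein-level
stringency at n = 8 + 8. Both modes are configuration switches.

**ORA.** Hypergeometric upper tail with the hit set intersected against a
user universe, BH across terms, GeneRatio = k/n. Protease enrichment uses
the same tail on a foreground of group-exclusive (plus significantly
changed) termini against the universe of all called termini, BH across
proteases; proteases annotated nowhere are omitted.

## Synthetic degradome generator

The generator's defaults are the study conditions: two groups of 8
subjects, 100 proteins (uniform length 120–500, 50% with a signal peptide
ending at residue 15–30), trypsin digestion with the proline rule, up to 2
missed cleavages (each retained with probability 0.3 per missed site),
identifiable peptide length 7–50.

Protein sequences use a **uniform residue composition** (an initiator M
aside). This is deliberate: planted cleavage sites are accepted by
thinning candidate non-K/R interior positions with the protease's
specificity likelihood ratio (acceptance ∝ site_rate × ∏ 20·p_model),
and under a uniform background the accepted windows follow the specificity
model's residue distribution *exactly*, making positional-preference
recovery a quantitative binomial test rather than a qualitative one. A
logistic acceptance link would compress strong preferences; the linear
thinning was chosen for this exactness. Planted P1 positions avoid K/R
(indistinguishable from trypsin) and the signal-peptide junction (by
definition the mature terminus).

The default protease roster: one shared protease (G/S preference at
P1/P1′, both groups), one case-exclusive protease (P1′ = A at probability
0.8, occurrence 0.7 per CASE sample, 0 in CTRL) and one shared protease
(P1′ = V) whose termini carry a −2 log₂ case effect. Per-row log₂
intensities are Normal: feature means ~ N(20, 2) (termini N(18, 2)),
within-group noise SD 0.5, and 5% of proteins carry a ±2 log₂ group
effect. Missingness is logistic in the true log₂ intensity
(intercept 10.6, slope −0.6 ⇒ ≈ 20% overall, intensity-dependent, MNAR),
which is what the CART imputation must withstand. Decoy semi-tryptic rows
(uniform-random non-K/R boundaries, sporadic presence) are added at 2% of
the truth-derived semi-tryptic rows, giving the terminus caller a
false-discovery floor to measure. All randomness derives from one seed
through named integer substreams, so outputs are byte-identical across
runs and platforms.

What the generator does **not** emulate: correlated peptide intensities
within a protein, retention-time or spectral effects, shared/homologous
sequences (mapping ambiguity), real residue composition, protein-level
FDR structure, PTMs other than termini. Passing recovery tests therefore
certifies the calling/statistics logic, not search-engine behaviour on
real spectra.

## Validation experiments

`terminome_miner.validation` re-derives the certifying quantities at run
time: digestion vs brute-force substring enumeration (200 random proteins,
length ≤ 60, mc ≤ 2, both proline conventions); moderated t at d₀ = 0 vs
the ordinary pooled t; Storey vs BH (π₀ = 1) and vs direct evaluation of
the defining minimum; ORA vs exhaustive enumeration of all C(10,5) draws;
enrichment p-values vs exact tail sums (N ≤ 30); type-I error and
empirical FDR on 100 null cohorts of 2,000 features; neo-N
recall/precision, protease-enrichment power (50 seeds, case-exclusive
protease, 60-protein cohorts — sized to give ≳130 truth termini per
protease while keeping the whole suite under a minute) and the matched
no-difference null; and P1′ preference recovery against a 99% binomial
interval of the planted 0.8.

The bundled tables under `data/reference/` transcribe the published
reference cohort's differential-protein tables and Venn/DEP totals, and a
small curated cleavage-site fixture covers the enzymes discussed for that
cohort (MMPs, BMP1, cathepsins, meprin, ADAMTS, BACE; e.g. P10451:185 by
MMP3/MMP7 and P98160:4195 by BMP1). The transcription preserved 43 + 36
table rows; the cohort's prose totals are 52 + 41, and the acceptance test
for those tallies records the discrepancy rather than hiding it.

## Numerical and degenerate-input conventions

Threshold inequalities are inclusive throughout. Tied intensities receive
average ranks. Zero-variance features shrink toward s₀²; a matrix with no
positive residual variance raises. PCA centers features and reports
variance fractions over min(n − 1, m) components; constant matrices
raise. Empty foregrounds, empty universes, empty p-value vectors and
all-missing columns raise with named messages. `min_presence` larger than
the group size empties the terminome stages without failing the run.

## Known limitations

Two-group designs only (no covariates or batch terms); single imputation;
exact-match peptide-to-protein mapping (no isoform disambiguation beyond
uniqueness); the terminus caller trusts search-engine peptide FDRs; the
cleavage database matcher is an exact positional join, so off-by-one
annotation conventions in external resources must be reconciled upstream.
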