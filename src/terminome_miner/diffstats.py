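"""Differential-abundance statistics for label-free intensity matrices.

The model: per feature g, log2 intensities in two groups of sizes n1, n2;
the pooled residual variance s_g^2 (df dg = n1 + n2 - 2) is shrunk toward a
prior variance s0^2 with prior degrees of freedom d0 estimated empirically
from the whole matrix (scaled-F moment matching via digamma/trigamma
inversion).  The moderated statistic

    t_g = (mean_case - mean_control) / (s~_g * sqrt(1/n1 + 1/n2)),
    s~_g^2 = (d0 s0^2 + dg s_g^2) / (d0 + dg),

is referred to a t distribution with d0 + dg degrees of freedom.  False
discovery control uses Storey q-values with a single-lambda pi0 estimate.

Matrices are pandas DataFrames, features x samples, log2 scale, NaN for
missing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.tree import DecisionTreeRegressor
from statsmodels.stats.multitest import multipletests

from .io_formats import PipelineConfig, SampleDesign

logger = logging.getLogger("terminome_miner")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize_by_class(matrix: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Quantile-normalize each class (group) independently.

    Within a class, each sample's observed values are replaced by the mean
    of the class's order statistics at the same rank; missing cells stay
    missing and are excluded from rank computation.  Samples with unequal
    numbers of observed values are aligned on the (r - 0.5)/n quantile scale
    by linear interpolation; tied values receive the average of their tied
    targets (average ranks interpolate linearly).
    """
    out = matrix.copy().astype(float)
    for group in design.groups:
        cols = [s for s in design.members(group) if s in matrix.columns]
        if len(cols) < 2:
            logger.warning("class %s has %d sample(s); left unnormalized",
                           group, len(cols))
            continue
        observed = {c: np.sort(matrix[c].dropna().to_numpy()) for c in cols}
        n_ref = max(len(v) for v in observed.values())
        if n_ref == 0:
            continue
        grid = (np.arange(n_ref) + 0.5) / n_ref
        ref = np.mean(
            [np.interp(grid, (np.arange(len(v)) + 0.5) / len(v), v)
             for v in observed.values() if len(v)],
            axis=0,
        )
        for c in cols:
            vals = matrix[c].to_numpy(dtype=float)
            mask = ~np.isnan(vals)
            n = mask.sum()
            if n == 0:
                continue
            ranks = stats.rankdata(vals[mask], method="average")
            new = vals.copy()
            new[mask] = np.interp((ranks - 0.5) / n, grid, ref)
            out[c] = new
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_cart(matrix: pd.DataFrame, seed: int, min_samples_leaf: int = 5,
                max_depth: int | None = None, sweeps: int = 1) -> pd.DataFrame:
    """Regression-tree imputation with predictive donor matching.

    For each sample column with missing cells, a regression tree predicts
    that column from all other columns on the rows where it is observed;
    each missing cell is then filled by drawing uniformly from the observed
    donor values in its terminal node.  Columns are visited in order of
    increasing missingness; already-imputed values feed later columns.
    Deterministic given ``seed``.
    """
    if matrix.isna().all(axis=None):
        raise ValueError("matrix entirely missing")
    all_missing_cols = matrix.columns[matrix.isna().all(axis=0)]
    if len(all_missing_cols):
        raise ValueError(f"sample column(s) entirely missing: {list(all_missing_cols)}")
    work = matrix.copy().astype(float)
    all_missing_rows = work.index[work.isna().all(axis=1)]
    if len(all_missing_rows):
        logger.warning("dropping %d feature(s) with no observed value",
                       len(all_missing_rows))
        work = work.drop(index=all_missing_rows)
    if not work.isna().any(axis=None):
        return work

    rng = np.random.default_rng(seed)
    miss_mask = work.isna()
    X = work.to_numpy(copy=True)
    # initialize with column means so predictor columns are complete
    col_means = np.nanmean(X, axis=0)
    miss = miss_mask.to_numpy()
    X[miss] = np.take(col_means, np.where(miss)[1])

    order = np.argsort(miss.sum(axis=0), kind="stable")
    for _ in range(sweeps):
        for j in order:
            m = miss[:, j]
            if not m.any():
                continue
            others = np.delete(np.arange(X.shape[1]), j)
            y_obs = work.to_numpy()[~m, j]
            tree = DecisionTreeRegressor(
                min_samples_leaf=min_samples_leaf, max_depth=max_depth,
                random_state=0)
            tree.fit(X[~m][:, others], y_obs)
            leaves_obs = tree.apply(X[~m][:, others])
            leaves_mis = tree.apply(X[m][:, others])
            donors_by_leaf = {
                leaf: y_obs[leaves_obs == leaf] for leaf in np.unique(leaves_obs)}
            filled = np.array(
                [rng.choice(donors_by_leaf[leaf]) for leaf in leaves_mis])
            X[m, j] = filled
    return pd.DataFrame(X, index=work.index, columns=work.columns)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

@dataclass
class ModerationParams:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    dg: float  # residual df per feature


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_moderation(s_sq: np.ndarray, dg: float) -> ModerationParams:
    """Moment-match a scaled F prior to the observed log sample variances."""
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq > 0
    if not positive.any():
        raise ValueError("all features have zero residual variance; "
                         "cannot estimate prior")
    z = np.log(s_sq[positive])
    e = z - digamma(dg / 2.0) + np.log(dg / 2.0)
    e_mean = e.mean()
    e_var = (e.var(ddof=1) - polygamma(1, dg / 2.0)) if e.size > 1 else 0.0
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # log-variances no more dispersed than chi-square sampling noise:
        # infinite prior df, all features share the mean sample variance
        d0 = np.inf
        s0_sq = s_sq[positive].mean()
    return ModerationParams(d0=d0, s0_sq=float(s0_sq), dg=dg)


def moderated_t(matrix: pd.DataFrame, design: SampleDesign,
                case_group: str | None = None,
                prior_df: float | None = None,
                prior_var: float | None = None) -> pd.DataFrame:
    """Per-feature moderated t-test on a complete log2 matrix.

    ``case_group`` defaults to the first group in sorted order; log2FC is
    mean(case) - mean(control).  ``prior_df`` overrides the estimated d0
    (0 recovers the ordinary pooled two-sample t; inf gives full shrinkage
    to ``prior_var`` or the estimated s0^2).  q_mod is left for
    :func:`storey_q`.
    """
    if matrix.isna().any(axis=None):
        raise ValueError("moderated_t requires a complete matrix (impute first)")
    case = case_group or design.groups[0]
    if case not in design.groups:
        raise ValueError(f"unknown case group {case!r}")
    control = [g for g in design.groups if g != case][0]
    ca = matrix[design.members(case)].to_numpy(dtype=float)
    co = matrix[design.members(control)].to_numpy(dtype=float)
    n1, n2 = ca.shape[1], co.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    dg = n1 + n2 - 2
    lfc = ca.mean(axis=1) - co.mean(axis=1)
    s_sq = ((n1 - 1) * ca.var(axis=1, ddof=1) + (n2 - 1) * co.var(axis=1, ddof=1)) / dg

    if prior_df is None:
        params = estimate_moderation(s_sq, dg)
    else:
        s0 = prior_var
        if s0 is None:
            s0 = estimate_moderation(s_sq, dg).s0_sq if prior_df > 0 else 0.0
        params = ModerationParams(d0=prior_df, s0_sq=s0, dg=dg)

    # total df capped at the pooled residual df of the whole matrix
    df_pooled = dg * len(s_sq)
    if np.isinf(params.d0):
        s_tilde_sq = np.full_like(s_sq, params.s0_sq)
        df_total = df_pooled
    else:
        s_tilde_sq = (params.d0 * params.s0_sq + dg * s_sq) / (params.d0 + dg)
        df_total = min(params.d0 + dg, df_pooled)

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        t_mod = np.where((se == 0) & (lfc != 0), np.sign(lfc) * np.inf, t_mod)
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = pd.DataFrame({
        "log2FC": lfc, "t_mod": t_mod, "p_mod": p_mod,
        "s_sq": s_sq, "s_tilde_sq": s_tilde_sq,
    }, index=matrix.index)
    out.attrs["moderation"] = params
    out.attrs["case_group"] = case
    out.attrs["control_group"] = control
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def storey_q(p_values, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    pi0 = min(1, #{p > lambda} / (m (1 - lambda)));
    q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j  (step-down minimum).
    With pi0 = 1 this is exactly Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def bh_adjust(p_values) -> np.ndarray:
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def call_deps(results: pd.DataFrame, config: PipelineConfig,
              mode: str = "protein") -> pd.DataFrame:
    """Assign up/down/ns status (inclusive thresholds).

    ``protein`` mode requires p_mod <= alpha_p AND q_mod <= alpha_q;
    ``terminus`` mode uses p_mod only, mirroring the terminus-level
    treatment where q-values did not reach significance.
    """
    if mode not in ("protein", "terminus"):
        raise ValueError(f"unknown mode {mode!r}")
    out = results.copy()
    sig = out["p_mod"] <= config.alpha_p
    if mode == "protein":
        sig &= out["q_mod"] <= config.alpha_q
    status = np.where(sig & (out["log2FC"] >= config.lfc_threshold), "up",
                      np.where(sig & (out["log2FC"] <= -config.lfc_threshold),
                               "down", "ns"))
    out["status"] = status
    return out


def differential_analysis(matrix: pd.DataFrame, design: SampleDesign,
                          config: PipelineConfig, mode: str = "protein",
                          case_group: str | None = None) -> pd.DataFrame:
    """moderated_t + storey_q + call_deps in one step (complete matrix)."""
    res = moderated_t(matrix, design, case_group=case_group)
    res["q_mod"] = storey_q(res["p_mod"].to_numpy(), lam=config.storey_lambda)
    return call_deps(res, config, mode=mode)


# ---------------------------------------------------------------------------
# PCA and over-representation
# ---------------------------------------------------------------------------

def pca_variance(matrix: pd.DataFrame) -> np.ndarray:
    """Variance fraction per principal component (samples as observations)."""
    if matrix.isna().any(axis=None):
        raise ValueError("pca_variance requires a complete matrix")
    X = matrix.to_numpy(dtype=float).T  # samples x features
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    svals = np.linalg.svd(Xc, compute_uv=False)
    var = svals ** 2
    k = min(X.shape[0] - 1, X.shape[1])
    var = var[:k]
    return var / var.sum()


def ora(hit_set: set, universe: set, gene_sets: dict[str, set]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hit_set`` against each term.

    p = P(X >= k) with population N = |universe|, K = |term & universe|
    successes and n = |hit_set| draws; BH-adjusted across terms.  GeneRatio
    is k/n.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hit_set <= universe:
        raise ValueError("hit_set must be a subset of the universe")
    N, n = len(universe), len(hit_set)
    records = []
    for term, members in gene_sets.items():
        K = len(members & universe)
        k = len(members & hit_set)
        p = stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        records.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                        "gene_ratio": k / n if n else 0.0, "p": float(p)})
    df = pd.DataFrame.from_records(records)
    if len(df):
        df["q_bh"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df
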