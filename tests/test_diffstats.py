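import math
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from terminome_miner.diffstats import (bh_adjust, call_deps,
                                       differential_analysis, impute_cart,
                                       moderated_t, ora, pca_variance,
                                       quantile_normalize_by_class, storey_q)
from terminome_miner.io_formats import PipelineConfig, SampleDesign


def matrix_for(design, values):
    return pd.DataFrame(values, columns=design.samples, dtype=float)


class TestQuantileNormalizeByClass:
    def test_hand_computed_rank_means(self):
        # one class of two samples: both become the rank-wise means
        d2 = SampleDesign(["a", "b", "x", "y"],
                          {"a": "G1", "b": "G1", "x": "G2", "y": "G2"})
        m = pd.DataFrame({"a": [1, 2, 3], "b": [4, 5, 6],
                          "x": [7, 7, 7], "y": [7, 7, 7]}, dtype=float)
        out = quantile_normalize_by_class(m, d2)
        assert list(out["a"]) == [2.5, 3.5, 4.5]
        assert list(out["b"]) == [2.5, 3.5, 4.5]

    def test_identical_samples_fixed_point(self, design4):
        m = matrix_for(design4, np.tile([[1.0], [5.0], [9.0]], 8))
        assert quantile_normalize_by_class(m, design4).equals(m)

    def test_sorted_observed_vectors_identical_within_class(self, design4):
        rng = np.random.default_rng(3)
        m = matrix_for(design4, rng.normal(20, 2, (50, 8)))
        m.iloc[rng.integers(0, 50, 12), rng.integers(0, 8, 12)] = np.nan
        out = quantile_normalize_by_class(m, design4)
        for group in design4.groups:
            cols = design4.members(group)
            sorted_vecs = [np.sort(out[c].dropna().to_numpy()) for c in cols]
            n = min(len(v) for v in sorted_vecs)
            for v in sorted_vecs[1:]:
                # equal-count samples must match exactly rank by rank
                if len(v) == len(sorted_vecs[0]):
                    np.testing.assert_allclose(v, sorted_vecs[0])

    def test_within_sample_rank_order_preserved(self, design4):
        rng = np.random.default_rng(4)
        m = matrix_for(design4, rng.normal(0, 1, (30, 8)))
        out = quantile_normalize_by_class(m, design4)
        for c in m.columns:
            assert (np.argsort(out[c].to_numpy(), kind="stable")
                    == np.argsort(m[c].to_numpy(), kind="stable")).all()

    def test_missing_cells_stay_missing(self, design4):
        rng = np.random.default_rng(5)
        m = matrix_for(design4, rng.normal(0, 1, (20, 8)))
        m.iloc[0, 0] = np.nan
        out = quantile_normalize_by_class(m, design4)
        assert math.isnan(out.iloc[0, 0])
        assert out.isna().sum().sum() == 1


class TestImputeCart:
    def test_complete_matrix_no_op(self, design4):
        rng = np.random.default_rng(6)
        m = matrix_for(design4, rng.normal(20, 1, (40, 8)))
        assert impute_cart(m, seed=1).equals(m)

    def test_deterministic_given_seed(self, design4):
        rng = np.random.default_rng(7)
        m = matrix_for(design4, rng.normal(20, 1, (40, 8)))
        m.iloc[rng.integers(0, 40, 15), rng.integers(0, 8, 15)] = np.nan
        a = impute_cart(m, seed=11)
        b = impute_cart(m, seed=11)
        assert a.equals(b)
        assert not a.isna().any(axis=None)

    def test_observed_cells_untouched(self, design4):
        rng = np.random.default_rng(8)
        m = matrix_for(design4, rng.normal(20, 1, (30, 8)))
        m.iloc[2, 3] = np.nan
        out = impute_cart(m, seed=2)
        mask = ~m.isna()
        assert out.where(mask).equals(m.where(mask))

    def test_single_donor_leaf_traced_by_hand(self):
        # column y mirrors column x; with fully grown trees and leaf size 1
        # the imputed cell must copy its nearest x-neighbour's observed y
        design = SampleDesign(["x", "y", "z"], {"x": "A", "y": "A", "z": "B"})
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0])
        m = pd.DataFrame({"x": x, "y": x * 10, "z": x + 1})
        m.loc[5, "y"] = np.nan
        out = impute_cart(m, seed=3, min_samples_leaf=1)
        # row 5 has x=32; the nearest observed donor is row 4 (x=16, y=160)
        assert out.loc[5, "y"] == 160.0

    def test_all_missing_column_error(self, design4):
        m = matrix_for(design4, np.ones((5, 8)))
        m.iloc[:, 0] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_cart(m, seed=1)

    def test_all_missing_feature_dropped_with_warning(self, design4, caplog):
        rng = np.random.default_rng(9)
        m = matrix_for(design4, rng.normal(20, 1, (10, 8)))
        m.iloc[4] = np.nan
        with caplog.at_level("WARNING"):
            out = impute_cart(m, seed=1)
        assert len(out) == 9 and 4 not in out.index


class TestModeratedT:
    def test_zero_prior_df_equals_pooled_t(self, design4):
        rng = np.random.default_rng(10)
        m = matrix_for(design4, rng.normal(20, 2, (100, 8)))
        res = moderated_t(m, design4, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(m.iloc[:, :4], m.iloc[:, 4:], axis=1)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p_mod"], p_ref, atol=1e-10)

    def test_hand_computed_example(self):
        design = SampleDesign(list("abcdef"),
                              dict(a="CASE", b="CASE", c="CASE",
                                   d="CTRL", e="CTRL", f="CTRL"))
        m = pd.DataFrame([[1, 2, 3, 2, 3, 4]], columns=design.samples, dtype=float)
        res = moderated_t(m, design, prior_df=0)
        assert res["t_mod"].iloc[0] == pytest.approx(-1.224744871, abs=1e-8)
        assert res["log2FC"].iloc[0] == pytest.approx(-1.0)

    def test_equal_means_give_t_zero_p_one(self, design4):
        m = matrix_for(design4, np.tile([[3.0, 7.0, 3.0, 7.0]], (1, 2)))
        m.iloc[0, :] = [1, 2, 3, 4, 1, 2, 3, 4]
        res = moderated_t(m, design4)
        assert res["t_mod"].iloc[0] == 0.0
        assert res["p_mod"].iloc[0] == 1.0

    def test_infinite_prior_df_limit_shrinks_to_s0(self, design4):
        rng = np.random.default_rng(11)
        m = matrix_for(design4, rng.normal(20, 2, (50, 8)))
        res = moderated_t(m, design4, prior_df=1e8)
        assert res["s_tilde_sq"].std() < 1e-6

    def test_matches_limma_ebayes(self, design4, tmp_path):
        """Independent oracle: the reference empirical-Bayes implementation."""
        rng = np.random.default_rng(12)
        sd = rng.uniform(0.3, 3.0, 60)
        m = matrix_for(design4, rng.normal(0, 1, (60, 8)) * sd[:, None] + 20)
        mat_path = tmp_path / "mat.tsv"
        m.to_csv(mat_path, sep="\t")
        script = tmp_path / "check.R"
        script.write_text(f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{mat_path}", row.names=1))
groups <- factor(c(rep("CASE",4), rep("CTRL",4)), levels=c("CTRL","CASE"))
fit <- eBayes(lmFit(m, model.matrix(~groups)))
write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),
            "{tmp_path}/r.tsv", sep="\\t", quote=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        res = moderated_t(m, design4)
        np.testing.assert_allclose(res["t_mod"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res["p_mod"], ref["p"], atol=1e-8)

    def test_zero_variance_everywhere_errors(self, design4):
        m = matrix_for(design4, np.ones((5, 8)))
        with pytest.raises(ValueError, match="variance"):
            moderated_t(m, design4)

    def test_incomplete_matrix_rejected(self, design4):
        m = matrix_for(design4, np.ones((5, 8)))
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            moderated_t(m, design4)


class TestStoreyQ:
    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=300)
        np.testing.assert_allclose(storey_q(p, pi0=1.0), bh_adjust(p))

    def test_defining_minimum_direct_evaluation(self):
        p = np.array([0.01, 0.02, 0.03, 0.9, 0.95, 0.99])
        q = storey_q(p, lam=0.5)
        m = len(p)
        pi0 = min(1.0, np.mean(p > 0.5) / 0.5)
        assert pi0 == 1.0
        expected = [min(pi0 * m * p[j] / (j + 1) for j in range(i, m))
                    for i in range(m)]
        np.testing.assert_allclose(np.sort(q), expected)

    def test_all_ones(self):
        np.testing.assert_allclose(storey_q(np.ones(10)), np.ones(10))

    def test_monotone_in_p_and_bounded_by_bh(self):
        rng = np.random.default_rng(14)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(size=100)])
        q = storey_q(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= bh_adjust(p) + 1e-12).all()  # pi0 <= 1 always

    def test_empty_error(self):
        with pytest.raises(ValueError):
            storey_q([])


class TestCallDeps:
    @pytest.mark.parametrize("lfc,p,q,expected", [
        (1.0, 0.01, 0.01, "up"),
        (-0.3, 0.001, 0.001, "ns"),     # fails fold-change
        (0.57, 0.05, 0.05, "up"),       # boundary inclusive
        (-0.57, 0.05, 0.05, "down"),
        (2.0, 0.01, 0.2, "ns"),         # fails q in protein mode
    ])
    def test_protein_mode_rules(self, config, lfc, p, q, expected):
        df = pd.DataFrame({"log2FC": [lfc], "p_mod": [p], "q_mod": [q]})
        assert call_deps(df, config, mode="protein")["status"].iloc[0] == expected

    def test_terminus_mode_ignores_q(self, config):
        df = pd.DataFrame({"log2FC": [2.0], "p_mod": [0.01], "q_mod": [0.9]})
        assert call_deps(df, config, mode="terminus")["status"].iloc[0] == "up"


class TestErrorRatesAndPower:
    def test_power_and_effect_recovery(self, design8, config):
        """delta = 2 on 5% of 2,000 features: q-mode sensitivity >= 0.8 and
        the average observed log2FC of true positives within 0.2 of delta."""
        rng = np.random.default_rng(15)
        n = 2000
        mu = rng.normal(20, 2, n)
        m = pd.DataFrame(mu[:, None] + rng.normal(0, 0.5, (n, 16)),
                         columns=design8.samples)
        affected = rng.random(n) < 0.05
        signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        m.iloc[:, :8] += (affected * signs * 2.0)[:, None]
        res = differential_analysis(m, design8, config, mode="protein")
        called = res["status"] != "ns"
        sens = (called & affected).sum() / affected.sum()
        assert sens >= 0.8
        tp = called & affected
        assert abs((res.loc[tp, "log2FC"] * signs[tp]).mean() - 2.0) <= 0.2


class TestPCA:
    def test_collinear_samples_give_pc1_everything(self):
        m = pd.DataFrame(np.outer([1.0, 2.0], [1, 2, 3, 4]),
                         index=["f1", "f2"], columns=list("abcd"))
        fractions = pca_variance(m)
        assert fractions[0] == pytest.approx(1.0)

    def test_isotropic_two_dim(self):
        # two orthogonal directions, equal variance
        m = pd.DataFrame([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]],
                         index=["f1", "f2"], columns=list("abcd"))
        np.testing.assert_allclose(pca_variance(m)[:2], [0.5, 0.5])

    def test_fractions_sum_to_one(self, design4):
        rng = np.random.default_rng(16)
        m = matrix_for(design4, rng.normal(0, 1, (30, 8)))
        assert pca_variance(m).sum() == pytest.approx(1.0)

    def test_constant_matrix_error(self, design4):
        with pytest.raises(ValueError):
            pca_variance(matrix_for(design4, np.ones((5, 8))))


class TestORA:
    UNIVERSE = set("ABCDEFGHIJ")
    HITS = set("ABCDE")

    def test_exact_term_probability(self):
        res = ora(self.HITS, self.UNIVERSE, {"T": set("ABCDE")})
        assert res["p"].iloc[0] == pytest.approx(1 / math.comb(10, 5))

    def test_disjoint_term_p_one(self):
        res = ora(self.HITS, self.UNIVERSE, {"T": set("FGHIJ")})
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Brute-force oracle: enumerate all C(10,5) draws of the hit set."""
        terms = {"T1": set("ABC"), "T2": set("AFGH"), "T3": set("BCDIJ")}
        res = ora(self.HITS, self.UNIVERSE, terms).set_index("term")
        draws = list(combinations(sorted(self.UNIVERSE), 5))
        for name, members in terms.items():
            k_obs = len(members & self.HITS)
            count = sum(1 for d in draws if len(members & set(d)) >= k_obs)
            assert res.loc[name, "p"] == pytest.approx(count / len(draws))

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            ora(set(), set(), {})

    def test_gene_ratio(self):
        res = ora(self.HITS, self.UNIVERSE, {"T": set("AB")})
        assert res["gene_ratio"].iloc[0] == pytest.approx(2 / 5)
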