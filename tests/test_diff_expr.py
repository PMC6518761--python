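import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirpair.diff_expr import bh_adjust, differential_test, fit_variance_prior
from mirpair.errors import GroupingError

from conftest import make_two_group


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_four_equal_spaced(self):
        # step-up: q_(i) = min_j>=i (4 p_(j) / j) = 0.04 for every rank here
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_permutation_invariant(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# per-feature tests
# ---------------------------------------------------------------------------

class TestDifferentialTest:
    def test_constant_feature_degenerate_not_exception(self):
        values = np.vstack([np.full(8, 5.0), np.arange(8, dtype=float)])
        expr, groups = make_two_group(values)
        for method in ["ttest", "wilcoxon", "moderated_t"]:
            de = differential_test(expr, groups, method)
            row = de.loc["F0"]
            assert row["statistic"] == 0.0
            assert row["p_value"] == 1.0
            assert not row["passes"]

    def test_separated_groups_pass(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([np.zeros(4), np.ones(4)]) + rng.normal(0, 1e-6, 8)
        expr, groups = make_two_group(values[None, :])
        de = differential_test(expr, groups, "ttest")
        row = de.iloc[0]
        assert row["log_ratio"] == pytest.approx(1.0, abs=1e-5)
        assert row["p_value"] < 1e-6
        assert row["passes"]

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, (100, 12)) * rng.uniform(0.5, 2, (100, 1))
        expr, groups = make_two_group(values)
        de = differential_test(expr, groups, "ttest")
        ref = stats.ttest_ind(values[:, 6:], values[:, :6], axis=1, equal_var=False)
        np.testing.assert_allclose(de["statistic"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(de["p_value"], ref.pvalue, atol=1e-10)

    def test_welch_reduces_to_student_when_variances_equal(self):
        # equal group sizes and identical sample variances: Welch df = 2n-2
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (30, 5))
        values = np.hstack([base, base + rng.normal(0, 1, (30, 1))])  # shift only
        expr, groups = make_two_group(values)
        de = differential_test(expr, groups, "ttest")
        ref = stats.ttest_ind(values[:, 5:], values[:, :5], axis=1, equal_var=True)
        np.testing.assert_allclose(de["p_value"], ref.pvalue, atol=1e-6)

    def test_wilcoxon_matches_scipy_exact_and_ties(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (20, 10))
        values[:5] = np.round(values[:5])  # force ties -> asymptotic path
        expr, groups = make_two_group(values)
        de = differential_test(expr, groups, "wilcoxon")
        for g in range(20):
            x, y = values[g, :5], values[g, 5:]
            ties = np.unique(np.concatenate([x, y])).size < 10
            method = "asymptotic" if ties else "exact"
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            assert de["p_value"].iloc[g] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_moderated_equals_pooled_t_when_variances_equal(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 10)
        values = np.tile(base, (50, 1)) + rng.normal(0, 2, 50)[:, None]
        expr, groups = make_two_group(values)
        de = differential_test(expr, groups, "moderated_t")
        ref = stats.ttest_ind(values[:, 5:], values[:, :5], axis=1, equal_var=True)
        np.testing.assert_allclose(de["statistic"], ref.statistic, atol=1e-8)

    def test_moderated_matches_limma(self, tmp_path):
        """Cross-check the variance-shrinkage t against Bioconductor limma."""
        rng = np.random.default_rng(5)
        sds = rng.uniform(0.2, 2.0, 60)
        values = rng.normal(0, 1, (60, 10)) * sds[:, None]
        values[:10, 5:] += 1.0
        expr, groups = make_two_group(values)
        mine = differential_test(expr, groups, "moderated_t")
        mat = tmp_path / "m.tsv"
        pd.DataFrame(values, index=expr.feature_ids, columns=expr.sample_ids).to_csv(
            mat, sep="\t"
        )
        script = tmp_path / "limma.R"
        script.write_text(
            f"""suppressMessages(library(limma))
x <- as.matrix(read.delim("{mat}", row.names=1))
design <- cbind(Intercept=1, Case=c(rep(0,5), rep(1,5)))
fit <- eBayes(lmFit(x, design))
write.csv(data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"]), "{tmp_path}/out.csv")
"""
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        np.testing.assert_allclose(mine["statistic"], ref["t"], atol=1e-6)
        np.testing.assert_allclose(mine["p_value"], ref["p"], atol=1e-6)

    def test_passes_monotone_in_thresholds(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, (200, 12))
        values[:40, 6:] += rng.uniform(0, 1.5, (40, 1))
        expr, groups = make_two_group(values)
        loose = differential_test(expr, groups, "ttest", 0.1, 0.2)["passes"]
        tight_p = differential_test(expr, groups, "ttest", 0.01, 0.2)["passes"]
        tight_r = differential_test(expr, groups, "ttest", 0.1, 0.8)["passes"]
        assert tight_p.sum() <= loose.sum()
        assert tight_r.sum() <= loose.sum()
        assert not (tight_p & ~loose).any()

    def test_small_group_rejected_and_deseq2_refused(self):
        values = np.arange(6, dtype=float)[None, :]
        expr, groups = make_two_group(values)  # 3 + 3 -> ok
        with pytest.raises(NotImplementedError):
            differential_test(expr, groups, "deseq2")
        expr2, groups2 = make_two_group(np.arange(3, dtype=float)[None, :])
        with pytest.raises(GroupingError):
            differential_test(expr2, groups2, "ttest")  # case group has 1 sample


def test_variance_prior_recovers_simulated_hyperparameters():
    """Moment-matching fit lands near the generating (d0, s0^2) at large m."""
    rng = np.random.default_rng(7)
    d0_true, s0_true, d = 6.0, 0.5, 10.0
    m = 20000
    s2 = s0_true * d0_true / rng.chisquare(d0_true, m)  # scaled inv-chi2 prior draws
    s2 = s2 * rng.chisquare(d, m) / d                    # sampling noise
    d0_hat, s0_hat = fit_variance_prior(s2, np.full(m, d))
    assert d0_hat == pytest.approx(d0_true, rel=0.15)
    assert s0_hat == pytest.approx(s0_true, rel=0.1)
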