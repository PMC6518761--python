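import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpair.datatypes import ExpressionMatrix, InteractionDB
from mirpair.errors import SampleMismatchError
from mirpair.pair_analysis import (
    annotate_pairs,
    correlate,
    correlate_de_pairs,
    support_stratified_summary,
)
from mirpair.synthetic import SOURCE_NAMES


def _expr(values, ids, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples))


class TestCorrelate:
    def test_perfect_anti_monotone(self):
        assert correlate([1, 2, 3], [3, 2, 1], "pearson") == pytest.approx(-1.0)
        assert correlate([1, 2, 3], [3, 2, 1], "spearman") == pytest.approx(-1.0)

    def test_kendall_printed_example(self):
        # pairs (1,2),(1,3),(2,3): concordant, concordant, discordant -> (2-1)/3
        assert correlate([1, 2, 3], [2, 1, 3], "kendall") == pytest.approx(1 / 3)

    def test_monotone_nonlinear(self):
        x, y = [1, 2, 3, 4], [1, 4, 9, 16]
        assert correlate(x, y, "spearman") == pytest.approx(1.0)
        assert correlate(x, y, "pearson") < 1.0

    def test_zero_variance_gives_nan(self):
        assert np.isnan(correlate([1, 1, 1], [1, 2, 3], "pearson"))

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(data=st.data())
    def test_symmetric_and_bounded(self, method, data):
        n = data.draw(st.integers(3, 12))
        x = data.draw(st.lists(st.floats(-50, 50), min_size=n, max_size=n))
        y = data.draw(st.lists(st.floats(-50, 50), min_size=n, max_size=n))
        r_xy = correlate(x, y, method)
        r_yx = correlate(y, x, method)
        if np.isnan(r_xy):
            assert np.isnan(r_yx)
        else:
            assert r_xy == pytest.approx(r_yx, abs=1e-12)
            assert -1.0 - 1e-12 <= r_xy <= 1.0 + 1e-12

    def test_pearson_equals_spearman_on_ranks(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        assert correlate(x, y, "pearson") == pytest.approx(correlate(x, y, "spearman"))


class TestCorrelateDePairs:
    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    def test_matches_scalar_scipy_path(self, method):
        rng = np.random.default_rng(1)
        mv, gv = rng.normal(8, 1, (4, 15)), rng.normal(8, 1, (6, 15))
        mirna = _expr(mv, [f"m{i}" for i in range(4)])
        gene = _expr(gv, [f"g{i}" for i in range(6)])
        out = correlate_de_pairs(mirna, gene, mirna.feature_ids, gene.feature_ids, method)
        assert len(out) == 24
        for _, row in out.iterrows():
            i = int(row["mirna"][1:]); j = int(row["gene"][1:])
            expected = correlate(mv[i], gv[j], method)
            assert row["r"] == pytest.approx(expected, abs=1e-12)

    def test_empty_de_list(self):
        rng = np.random.default_rng(2)
        m = _expr(rng.normal(0, 1, (2, 5)), ["m0", "m1"])
        g = _expr(rng.normal(0, 1, (2, 5)), ["g0", "g1"])
        assert correlate_de_pairs(m, g, [], ["g0"]).empty

    def test_sample_mismatch_names_offenders(self):
        m = _expr(np.zeros((1, 3)) + [[1, 2, 3]], ["m0"], ["a", "b", "c"])
        g = _expr(np.zeros((1, 3)) + [[1, 2, 3]], ["g0"], ["a", "b", "d"])
        with pytest.raises(SampleMismatchError, match="d"):
            correlate_de_pairs(m, g, ["m0"], ["g0"])

    def test_sample_reordering_is_repaired(self):
        rng = np.random.default_rng(3)
        mv = rng.normal(0, 1, (1, 8))
        m = _expr(mv, ["m0"], [f"s{j}" for j in range(8)])
        g = _expr(-mv[:, ::-1], ["g0"], [f"s{j}" for j in reversed(range(8))])
        out = correlate_de_pairs(m, g, ["m0"], ["g0"])
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(4)
        m = _expr(rng.normal(0, 1, (5, 20)), [f"m{i}" for i in range(5)])
        g = _expr(rng.normal(0, 1, (5, 20)), [f"g{i}" for i in range(5)])
        loose = correlate_de_pairs(m, g, m.feature_ids, g.feature_ids, cutoff=-0.3)
        tight = correlate_de_pairs(m, g, m.feature_ids, g.feature_ids, cutoff=-0.5)
        assert tight["passes_cutoff"].sum() <= loose["passes_cutoff"].sum()
        assert not (tight["passes_cutoff"] & ~loose["passes_cutoff"]).any()

    def test_planted_pair_passes(self, default_bundle):
        b = default_bundle
        mirna, gene = b.truth.planted_pairs[0]
        out = correlate_de_pairs(b.mirna_expr, b.gene_expr, [mirna], [gene])
        assert out["r"].iloc[0] <= -0.5
        assert bool(out["passes_cutoff"].iloc[0])


def _toy_db(support_counts, validated=None):
    validated = validated or [False] * len(support_counts)
    rows = []
    for i, (s, v) in enumerate(zip(support_counts, validated)):
        flags = {name: j < s for j, name in enumerate(SOURCE_NAMES)}
        rows.append({"mirna": f"m{i}", "gene": f"g{i}", **flags, "validated": v})
    return InteractionDB(pd.DataFrame(rows), list(SOURCE_NAMES))


class TestAnnotatePairs:
    def test_threshold_boundary(self):
        db = _toy_db([3])
        pairs = pd.DataFrame({"mirna": ["m0"], "gene": ["g0"], "r": [-0.6],
                              "method": "pearson", "passes_cutoff": [True]})
        kept = annotate_pairs(pairs, db, min_support=3)
        assert len(kept) == 1 and kept["support_count"].iloc[0] == 3
        assert annotate_pairs(pairs, db, min_support=4).empty

    def test_absent_pair_dropped_unless_min_support_zero(self):
        db = _toy_db([2])
        pairs = pd.DataFrame({"mirna": ["mX"], "gene": ["gX"], "r": [-0.9],
                              "method": "pearson", "passes_cutoff": [True]})
        assert annotate_pairs(pairs, db, min_support=1).empty
        kept = annotate_pairs(pairs, db, min_support=0)
        assert len(kept) == 1 and kept["support_count"].iloc[0] == 0

    def test_validated_kept_regardless_of_support(self):
        db = _toy_db([0], validated=[True])
        pairs = pd.DataFrame({"mirna": ["m0"], "gene": ["g0"], "r": [-0.6],
                              "method": "pearson", "passes_cutoff": [True]})
        assert annotate_pairs(pairs, db, min_support=1, require_validated=False).empty
        assert len(annotate_pairs(pairs, db, min_support=1, require_validated=True)) == 1

    def test_support_sweep_matches_cumulative_histogram(self):
        rng = np.random.default_rng(5)
        supports = rng.integers(0, 9, 20).tolist()
        db = _toy_db(supports)
        pairs = pd.DataFrame({"mirna": [f"m{i}" for i in range(20)],
                              "gene": [f"g{i}" for i in range(20)],
                              "r": [-0.6] * 20, "method": "pearson",
                              "passes_cutoff": [True] * 20})
        for threshold in range(9):
            expected = sum(1 for s in supports if s >= threshold)
            assert len(annotate_pairs(pairs, db, min_support=threshold)) == expected


class TestSupportSummary:
    def test_all_positive_correlations(self):
        pairs = pd.DataFrame({"r": [0.5] * 6, "support_count": [0, 0, 1, 3, 5, 8]})
        table = support_stratified_summary(pairs)
        assert (table["n_below"] == 0).all()
        assert (table["proportion"] == 0).all()

    def test_hand_computed_table(self):
        pairs = pd.DataFrame(
            {"r": [-0.6, -0.4, -0.2, 0.1, -0.35, -0.05, -0.55, 0.3, -0.31, -0.8],
             "support_count": [0, 0, 0, 0, 1, 2, 3, 3, 4, 8]}
        )
        table = support_stratified_summary(pairs, r_thresholds=[-0.3],
                                           support_thresholds=[1, 3])
        by = {row["stratum"]: row for _, row in table.iterrows()}
        # support=0: r in {-0.6,-0.4,-0.2,0.1}; below -0.3: two of four
        assert by["support=0"]["n_pairs"] == 4 and by["support=0"]["n_below"] == 2
        # support>=1: six pairs; below -0.3: -0.35, -0.55, -0.31, -0.8
        assert by["support>=1"]["n_pairs"] == 6 and by["support>=1"]["n_below"] == 4
        # support>=3: four pairs; below -0.3: -0.55, -0.31, -0.8
        assert by["support>=3"]["n_pairs"] == 4 and by["support>=3"]["n_below"] == 3

    def test_nested_thresholds_monotone(self):
        rng = np.random.default_rng(6)
        pairs = pd.DataFrame({"r": rng.uniform(-1, 1, 200),
                              "support_count": rng.integers(0, 9, 200)})
        table = support_stratified_summary(pairs, r_thresholds=[-0.1, -0.3, -0.5])
        for stratum in table["stratum"].unique():
            sub = table[table["stratum"] == stratum].set_index("r_threshold")
            assert sub.loc[-0.5, "n_below"] <= sub.loc[-0.3, "n_below"] <= sub.loc[-0.1, "n_below"]

    def test_nan_correlations_excluded(self):
        pairs = pd.DataFrame({"r": [np.nan, -0.9], "support_count": [3, 3]})
        table = support_stratified_summary(pairs, r_thresholds=[-0.5], support_thresholds=[3])
        row = table[table["stratum"] == "support>=3"].iloc[0]
        assert row["n_pairs"] == 1 and row["n_below"] == 1


def test_planted_pair_recall_and_precision_at_cutoff(default_bundle):
    """With beta 0.9 and noise sd 0.3 at n=30, planted pairs separate cleanly at r <= -0.5."""
    b = default_bundle
    de_mirnas = b.truth.de_mirnas
    de_genes = b.truth.de_genes
    pairs = correlate_de_pairs(b.mirna_expr, b.gene_expr, de_mirnas, de_genes)
    annotated = b.db.lookup(pairs)
    kept = annotated[annotated["passes_cutoff"] & (annotated["support_count"] >= 1)]
    found = set(zip(kept["mirna"], kept["gene"]))
    planted = set(b.truth.planted_pairs)
    recall = len(found & planted) / len(planted)
    precision = len(found & planted) / len(found)
    assert recall >= 0.9
    assert precision >= 0.9
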