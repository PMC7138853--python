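"""Differential expression, ANOVA, BH, distances, clustering and PCA."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from tmtquant.stats import (
    anova_oneway,
    bh_adjust,
    differential_expression,
    hierarchical_cluster,
    pca_scores,
    resolve_contrast,
    uncentered_correlation_distance,
    uncentered_distance_matrix,
)


class TestDifferentialExpression:
    def test_closed_form_t(self):
        m = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], columns=list("abcdef"))
        res = differential_expression(m, ["a", "b", "c"], ["d", "e", "f"])
        assert res["log2fc"].iloc[0] == pytest.approx(-3.0)
        assert res["t"].iloc[0] == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))
        assert res["p"].iloc[0] == pytest.approx(
            2 * sps.t.sf(3.0 / math.sqrt(2.0 / 3.0), 4))

    def test_identical_groups_give_p_one(self):
        m = pd.DataFrame([[1.0, 2, 3, 1, 2, 3]], columns=list("abcdef"))
        res = differential_expression(m, ["a", "b", "c"], ["d", "e", "f"])
        assert res["log2fc"].iloc[0] == 0.0

    def test_zero_variance_identical_values(self):
        m = pd.DataFrame([[2.0, 2, 2, 2]], columns=list("abcd"))
        res = differential_expression(m, ["a", "b"], ["c", "d"])
        assert res["p"].iloc[0] == 1.0
        assert res["t"].iloc[0] == 0.0

    def test_empty_group_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            differential_expression(toy_matrix, [], ["s0"])

    def test_untested_proteins_reported(self):
        m = pd.DataFrame([[1.0, np.nan, np.nan, 2, 3, 4]],
                         columns=list("abcdef"))
        res = differential_expression(m, ["a", "b", "c"], ["d", "e", "f"])
        assert not res["tested"].iloc[0]
        assert np.isnan(res["q"].iloc[0])

    @given(st.integers(0, 500))
    def test_antisymmetric_in_group_order(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(size=(5, 6)), columns=list("abcdef"))
        fwd = differential_expression(m, ["a", "b", "c"], ["d", "e", "f"])
        rev = differential_expression(m, ["d", "e", "f"], ["a", "b", "c"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["t"], -rev["t"])
        assert np.allclose(fwd["p"], rev["p"])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_enumeration_oracle(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(0, 500))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(10)
        perm = rng.permutation(10)
        q1 = bh_adjust(p)
        q2 = bh_adjust(p[perm])
        assert np.allclose(q1[perm], q2)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestAnova:
    def test_flat_groups_give_f_zero(self):
        m = pd.DataFrame([[1.0, 2, 1, 2, 1, 2]], columns=list("abcdef"))
        groups = pd.Series(dict(zip("abcdef",
                                    ["g1", "g1", "g2", "g2", "g3", "g3"])))
        res = anova_oneway(m, groups)
        assert res["F"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_mean_squares(self):
        m = pd.DataFrame([[1.0, 2, 3, 5, 6, 9]], columns=list("abcdef"))
        groups = pd.Series(dict(zip("abcdef",
                                    ["g1", "g1", "g2", "g2", "g3", "g3"])))
        res = anova_oneway(m, groups)
        f_scipy, p_scipy = sps.f_oneway([1.0, 2], [3.0, 5], [6.0, 9])
        assert res["F"].iloc[0] == pytest.approx(f_scipy)
        assert res["p"].iloc[0] == pytest.approx(p_scipy)

    def test_degenerate_constant_everywhere(self):
        m = pd.DataFrame([[3.0] * 6], columns=list("abcdef"))
        groups = pd.Series(dict(zip("abcdef",
                                    ["g1", "g1", "g2", "g2", "g3", "g3"])))
        with pytest.warns(UserWarning, match="zero variance"):
            res = anova_oneway(m, groups)
        assert res["p"].iloc[0] == 1.0

    def test_two_groups_rejected(self, toy_matrix):
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4,
                           index=toy_matrix.columns)
        with pytest.raises(ValueError, match=">= 3 groups"):
            anova_oneway(toy_matrix, groups)


class TestUncenteredCorrelation:
    def test_self_distance_zero(self):
        assert uncentered_correlation_distance([1.0, 2, 3], [1.0, 2, 3]) == \
            pytest.approx(0.0)

    def test_orthogonal_distance_one(self):
        assert uncentered_correlation_distance([1.0, 0], [0.0, 1]) == \
            pytest.approx(1.0)

    def test_formula_example(self):
        d = uncentered_correlation_distance([1.0, 0], [1.0, 1])
        assert d == pytest.approx(1 - 1 / math.sqrt(2))

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError, match="zero-norm"):
            uncentered_correlation_distance([0.0, 0], [1.0, 1])

    def test_pairwise_complete_positions(self):
        d = uncentered_correlation_distance([1.0, np.nan, 2],
                                            [2.0, 5.0, 4])
        assert d == pytest.approx(0.0)    # proportional on shared positions

    @given(st.floats(0.1, 50.0), st.integers(0, 100))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=6) + 3, rng.normal(size=6) + 3
        d1 = uncentered_correlation_distance(x, y)
        d2 = uncentered_correlation_distance(c * x, y)
        assert d1 == pytest.approx(d2, abs=1e-9)


def _brute_complete_linkage(D):
    """Independent O(n^3) agglomeration with smallest-index tie-break."""
    n = len(D)
    clusters = {i: [i] for i in range(n)}
    ids = {i: i for i in range(n)}
    merges = []
    next_id = n
    dist = {(i, j): D[i][j] for i in range(n) for j in range(i + 1, n)}
    active = sorted(clusters)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = max(D[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((min(ids[i], ids[j]), max(ids[i], ids[j]), d))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        ids[next_id] = next_id
        active = sorted(clusters)
        next_id += 1
    return merges


class TestHierarchicalCluster:
    def test_two_items_single_merge(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [1.0, 1.0]})
        res = hierarchical_cluster(m, axis="samples", median_center=False,
                                   min_shared=2)
        assert res.linkage.shape == (1, 4)
        assert res.linkage[0, 2] == pytest.approx(1 - 1 / math.sqrt(2))

    def test_matches_bruteforce_agglomeration(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(2, 1, (6, 5)),
                         columns=[f"s{j}" for j in range(5)])
        res = hierarchical_cluster(m, axis="samples", median_center=False)
        D = uncentered_distance_matrix(m.values.T)
        brute = _brute_complete_linkage(D.tolist())
        for k, (a, b, h) in enumerate(brute):
            assert res.linkage[k, 0] == a
            assert res.linkage[k, 1] == b
            assert res.linkage[k, 2] == pytest.approx(h)

    def test_duplicate_item_merges_first_at_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(3, 1, 10)
        m = pd.DataFrame({"a": base, "b": base,
                          "c": rng.normal(3, 1, 10),
                          "d": rng.normal(-3, 1, 10)})
        res = hierarchical_cluster(m, axis="samples", median_center=False)
        assert res.linkage[0, 0] == 0 and res.linkage[0, 1] == 1
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_all_missing_item_dropped(self):
        m = pd.DataFrame({"a": [1.0, 2], "b": [np.nan, np.nan],
                          "c": [1.0, 3]})
        with pytest.warns(UserWarning, match="all-missing"):
            res = hierarchical_cluster(m, axis="samples",
                                       median_center=False, min_shared=1)
        assert res.labels == ["a", "c"]

    def test_newick_contains_all_leaves(self, toy_matrix):
        res = hierarchical_cluster(toy_matrix, axis="samples")
        for s in toy_matrix.columns:
            assert s in res.newick
        assert res.newick.endswith(";")
        assert sorted(res.leaf_order) == sorted(toy_matrix.columns)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.arange(1, 6, dtype=float)
        v = np.array([1.0, -2.0, 0.5])
        m = pd.DataFrame(np.outer(u, v) + 5.0,
                         columns=["a", "b", "c"])
        # rank-1 after centering across samples
        scores, evr = pca_scores(m.T if False else m, n_components=3)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_isometry_with_all_components(self, toy_matrix):
        scores, _ = pca_scores(toy_matrix, n_components=8)
        X = toy_matrix.values.T
        Xc = X - X.mean(axis=0)
        d_orig = np.linalg.norm(Xc[0] - Xc[1])
        d_pca = np.linalg.norm(scores.iloc[0] - scores.iloc[1])
        assert d_orig == pytest.approx(d_pca)

    def test_missing_values_rejected(self, toy_matrix):
        m = toy_matrix.copy()
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputation"):
            pca_scores(m)

    def test_group_separation_on_constructed_cohort(self):
        rng = np.random.default_rng(0)
        n = 100
        base = rng.normal(25, 1, n)
        ga = base[:, None] + rng.normal(0, 0.3, (n, 6))
        gb = base[:, None] + rng.normal(0, 0.3, (n, 6))
        gb[:30] += 2.0
        m = pd.DataFrame(np.hstack([ga, gb]),
                         columns=[f"a{i}" for i in range(6)]
                         + [f"b{i}" for i in range(6)])
        scores, _ = pca_scores(m, n_components=2)
        from sklearn.metrics import silhouette_score
        labels = [0] * 6 + [1] * 6
        assert silhouette_score(scores.values[:, :1], labels) > 0.5


class TestResolveContrast:
    def test_union_syntax(self):
        ann = pd.DataFrame({"sample_id": ["x", "y", "z"],
                            "group": ["tnbc", "spindle", "normal"]})
        ga, gb = resolve_contrast(ann, "tnbc+spindle:normal")
        assert ga == ["x", "y"] and gb == ["z"]

    def test_unknown_group_errors(self):
        ann = pd.DataFrame({"sample_id": ["x"], "group": ["tnbc"]})
        with pytest.raises(ValueError, match="unknown groups"):
            resolve_contrast(ann, "tnbc:nope")
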