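"""Normalization, differential expression, gene-set statistics, and the
PCA/clustering primitives."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipodriver.exprstats import (
    ExpressionMatrix,
    differential_expression,
    embed_and_cluster,
    geneset_shift_test,
    hypergeometric_enrichment,
    multiple_test_adjust,
    size_factor_normalize,
    _rank_sum_test,
)


def matrix_from(values: np.ndarray, groups=None, normalized=False):
    df = pd.DataFrame(values,
                      index=[f"G{i}" for i in range(values.shape[0])],
                      columns=[f"S{j}" for j in range(values.shape[1])])
    g = None
    if groups is not None:
        g = pd.Series(groups, index=df.columns)
    return ExpressionMatrix(values=df, groups=g, normalized=normalized)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = matrix_from(np.tile([[10.0], [20.0], [5.0]], (1, 2)))
        _, factors = size_factor_normalize(m)
        assert np.allclose(factors, 1.0)

    def test_pure_depth_effect_recovered(self):
        base = np.array([10.0, 25.0, 40.0, 5.0])
        m = matrix_from(np.column_stack([base, 2 * base]))
        _, factors = size_factor_normalize(m)
        assert factors["S1"] / factors["S0"] == pytest.approx(2.0)

    def test_factors_invariant_under_gene_reordering(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(50, (40, 6)).astype(float) + 1
        m = matrix_from(vals)
        _, f1 = size_factor_normalize(m)
        shuffled = ExpressionMatrix(values=m.values.sample(frac=1, random_state=0))
        _, f2 = size_factor_normalize(shuffled)
        assert np.allclose(f1, f2)

    def test_no_common_gene_raises_with_advice(self):
        m = matrix_from(np.array([[0.0, 5.0], [5.0, 0.0]]))
        with pytest.raises(ValueError, match="pseudocount"):
            size_factor_normalize(m)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(30, (50, 5)).astype(float) + 1
        normed, _ = size_factor_normalize(matrix_from(vals))
        _, refit = size_factor_normalize(normed)
        assert np.allclose(refit, 1.0, atol=1e-9)


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        count += abs(s - mu) >= abs(obs - mu) - 1e-9
        total += 1
    return count / total


class TestWilcoxon:
    def test_textbook_exact_p(self):
        # A=(1,2,3) vs B=(4,5,6): the two one-sided extremes of C(6,3)=20
        _, p = _rank_sum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6), (8, 8)])
    def test_exact_path_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            _, p = _rank_sum_test(x, y)
            assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-9)

    def test_all_tied_input_returns_one(self):
        _, p = _rank_sum_test(np.array([3.0, 3, 3]), np.array([3.0, 3, 3]))
        assert p == 1.0


class TestDifferentialExpression:
    def _cohort(self, shift=0.0, n=10, genes=50, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.poisson(40, (genes, n)).astype(float)
        b = rng.poisson(40 * 2**shift, (genes, n)).astype(float)
        return matrix_from(np.column_stack([a, b]),
                           groups=["WD"] * n + ["DD"] * n, normalized=True)

    def test_group_swap_antisymmetry(self):
        m = self._cohort(shift=1.0)
        ab = differential_expression(m, "WD", "DD")
        ba = differential_expression(m, "DD", "WD")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_constant_gene_gets_p_one_fc_zero(self):
        m = self._cohort()
        m.values.iloc[0] = 7.0
        res = differential_expression(m, "WD", "DD")
        assert res["pvalue"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0

    def test_adjusted_never_below_raw(self):
        res = differential_expression(self._cohort(shift=0.5), "WD", "DD")
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()

    def test_requires_three_per_group(self):
        m = matrix_from(np.ones((5, 4)), groups=["WD", "WD", "DD", "DD"])
        with pytest.raises(ValueError, match=">= 3 samples"):
            differential_expression(m, "WD", "DD")


class TestMultipleTestAdjust:
    def test_bonferroni_closed_form(self):
        assert multiple_test_adjust([0.03, 0.5], "bonferroni")[0] == pytest.approx(0.06)
        assert (multiple_test_adjust([0.9, 0.8], "bonferroni") <= 1.0).all()

    def test_bh_equal_pvalues_fixed_point(self):
        p = np.full(7, 0.04)
        assert np.allclose(multiple_test_adjust(p, "BH"), 0.04)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 200)
        assert np.allclose(multiple_test_adjust(p, "BH"),
                           multipletests(p, method="fdr_bh")[1])
        assert np.allclose(multiple_test_adjust(p, "bonferroni"),
                           multipletests(p, method="bonferroni")[1])

    def test_output_bounded_and_order_preserving(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100)
        adj = multiple_test_adjust(p, "BH")
        assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            multiple_test_adjust([0.5, 1.2])


class TestEnrichment:
    def test_query_equals_universe_set(self):
        uni = [f"G{i}" for i in range(10)]
        res = hypergeometric_enrichment(uni, {"all": uni}, uni)
        assert res.loc["all", "pvalue"] == pytest.approx(1.0)

    def test_single_table_enumeration(self):
        # universe 20, set 10, query 10, overlap 10 -> 1 / C(20,10)
        uni = [f"G{i}" for i in range(20)]
        res = hypergeometric_enrichment(uni[:10], {"s": uni[:10]}, uni)
        from math import comb
        assert res.loc["s", "pvalue"] == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_p_decreases_with_overlap(self):
        uni = [f"G{i}" for i in range(40)]
        ps = []
        for k in range(1, 11):
            query = uni[:10]
            gene_set = uni[:k] + uni[20:20 + (10 - k)]
            res = hypergeometric_enrichment(query, {"s": gene_set}, uni)
            ps.append(res.loc["s", "pvalue"])
        assert (np.diff(ps) <= 1e-12).all()

    def test_disjoint_set_skipped_with_warning(self):
        uni = ["A", "B"]
        with pytest.warns(UserWarning, match="skipped"):
            res = hypergeometric_enrichment(["A"], {"out": ["X", "Y"]}, uni)
        assert res.empty


class TestGenesetShift:
    def test_identical_groups_give_p_one(self):
        vals = np.tile(np.arange(1.0, 5.0)[:, None], (1, 6))
        m = matrix_from(vals, groups=["WD"] * 3 + ["DD"] * 3, normalized=True)
        res = geneset_shift_test(m, {"s": ["G0", "G1"]}, "WD", "DD")
        assert res.loc["s", "pvalue"] == 1.0

    def test_invariant_to_genes_outside_the_set(self):
        rng = np.random.default_rng(5)
        vals = rng.poisson(30, (20, 12)).astype(float)
        groups = ["WD"] * 6 + ["DD"] * 6
        m1 = matrix_from(vals, groups=groups, normalized=True)
        vals2 = vals.copy()
        vals2[10:] *= 100  # perturb only non-set genes
        m2 = matrix_from(vals2, groups=groups, normalized=True)
        sets = {"s": ["G0", "G1", "G2"]}
        pd.testing.assert_frame_equal(geneset_shift_test(m1, sets, "WD", "DD"),
                                      geneset_shift_test(m2, sets, "WD", "DD"))

    def test_planted_shift_is_detected(self):
        """A 4-fold set shift at n=10 vs 10 reaches p < 0.01 in >=95% of seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.poisson(40, (5, 10)).astype(float)
            b = rng.poisson(160, (5, 10)).astype(float)
            m = matrix_from(np.column_stack([a, b]),
                            groups=["WD"] * 10 + ["DD"] * 10, normalized=True)
            res = geneset_shift_test(m, {"s": [f"G{i}" for i in range(5)]},
                                     "WD", "DD")
            hits += res.loc["s", "pvalue"] < 0.01
        assert hits >= 48

    def test_tiny_set_rejected(self):
        m = matrix_from(np.ones((3, 6)), groups=["WD"] * 3 + ["DD"] * 3)
        with pytest.raises(ValueError, match="fewer than 2"):
            geneset_shift_test(m, {"s": ["G0"]}, "WD", "DD")


class TestEmbedAndCluster:
    def _two_blobs(self, sep=8.0, n=10, genes=30, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(20, 1, (genes, n))
        b = rng.normal(20 + sep, 1, (genes, n))
        return matrix_from(np.abs(np.column_stack([a, b])), normalized=True)

    def test_separated_groups_recovered(self):
        m = self._two_blobs()
        res = embed_and_cluster(m, k=2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_variance_explained_is_sorted(self):
        res = embed_and_cluster(self._two_blobs(), k=2)
        assert (np.diff(res.variance_ratio) <= 1e-9).all()
        assert res.variance_ratio.sum() <= 1.0 + 1e-9

    def test_duplicating_samples_duplicates_labels(self):
        m = self._two_blobs(n=5)
        dup_vals = pd.concat([m.values, m.values.add_suffix("_dup", axis=1)], axis=1)
        res = embed_and_cluster(ExpressionMatrix(values=dup_vals, normalized=True), k=2)
        orig = res.labels.iloc[:10].to_numpy()
        dup = res.labels.iloc[10:].to_numpy()
        assert (orig == dup).all()

    def test_sample_order_invariance_up_to_relabel(self):
        m = self._two_blobs(seed=3)
        res1 = embed_and_cluster(m, k=2)
        perm = m.values.sample(frac=1, axis=1, random_state=7)
        res2 = embed_and_cluster(ExpressionMatrix(values=perm, normalized=True), k=2)
        l1 = res1.labels[perm.columns].to_numpy()
        l2 = res2.labels.to_numpy()
        agree = (l1 == l2).mean()
        assert agree in (0.0, 1.0)  # identical partition up to label swap

    def test_k_larger_than_samples_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            embed_and_cluster(self._two_blobs(n=2), k=5)
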