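import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import gdttc
from gdttc.containers import ValidationError
from gdttc.network import UndefinedCorrelationError, spearman_p

from oracles import exhaustive_spearman_pvalue


class TestSpearmanP:
    def test_perfect_monotone_gives_p_zero(self):
        r, t, p = spearman_p([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r == 1.0 and p == 0.0 and np.isinf(t)

    def test_t_and_p_against_numeric_integration(self):
        """r=0.9, n=12: t = 0.9*sqrt(10/0.19); p by integrating the t density."""
        # build rank data achieving rho = 0.9 at n = 12: sum d^2 = 28.6 not integer;
        # instead feed vectors and check the formula against independent numerics.
        rng = np.random.default_rng(1)
        x = rng.standard_normal(12)
        y = 0.8 * x + 0.3 * rng.standard_normal(12)
        r, t, p = spearman_p(x, y)
        assert t == pytest.approx(r * np.sqrt(10 / (1 - r**2)))
        density = lambda u: stats.t.pdf(u, 10)
        tail, _ = integrate.quad(density, abs(t), np.inf)
        assert p == pytest.approx(2 * tail, rel=1e-8)
        # the formula's anchor value from the definition
        assert 0.9 * np.sqrt(10 / (1 - 0.81)) == pytest.approx(6.529, abs=1e-3)

    def test_invariant_under_strictly_increasing_transform(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        base = spearman_p(x, y)
        warped = spearman_p(x, np.exp(3 * y) + 5)
        assert base == pytest.approx(warped)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_p([1, 2, 3, 4], [2, 2, 2, 2])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_p([1, 2, np.nan, 4], [1, 2, 3, np.nan])

    def test_significance_calls_match_exhaustive_permutations(self, rng):
        """t-approximation agrees with the exact permutation p at alpha=0.05
        on >= 95% of random n=7 instances."""
        agree = 0
        trials = 40
        for _ in range(trials):
            x = rng.standard_normal(7)
            y = rng.standard_normal(7)
            _, _, p_t = spearman_p(x, y)
            p_exact = exhaustive_spearman_pvalue(x, y)
            agree += (p_t < 0.05) == (p_exact < 0.05)
        assert agree / trials >= 0.95


def _pair_matrices(rng, n_genes=20, n_donors=40, planted=3, r=0.8):
    donors = [f"D{i}" for i in range(n_donors)]
    A = rng.standard_normal((n_genes, n_donors))
    B = rng.standard_normal((n_genes, n_donors))
    for i in range(planted):  # genes i in A and i in B strongly coupled
        shared = rng.standard_normal(n_donors)
        alpha = np.sqrt(r / (1 - r))
        A[i] = (A[i] + alpha * shared) / np.sqrt(1 + alpha**2)
        B[i] = (B[i] + alpha * shared) / np.sqrt(1 + alpha**2)
    genes = [f"G{i:02d}" for i in range(n_genes)]
    ea = gdttc.ExpressionMatrix(pd.DataFrame(A, index=genes, columns=donors), tissue="T1")
    eb = gdttc.ExpressionMatrix(pd.DataFrame(B, index=genes, columns=donors), tissue="T2")
    return ea, eb


class TestCallEdges:
    def test_dual_rule_keeps_strong_pairs_and_drops_decor_failures(self, rng):
        ea, eb = _pair_matrices(rng)
        # decorrelated copies identical -> planted pairs pass both thresholds
        edges = gdttc.call_edges(ea, eb, ea, eb)
        called = {(r.gene_a, r.gene_b) for r in edges.records}
        assert {("G00", "G00"), ("G01", "G01"), ("G02", "G02")} <= called
        # destroy the decorrelated signal -> dual rule rejects everything
        noise_a, noise_b = _pair_matrices(np.random.default_rng(99), planted=0)
        edges2 = gdttc.call_edges(ea, eb, noise_a, noise_b)
        assert edges2.n_edges == 0

    def test_symmetric_in_tissue_order(self, rng):
        ea, eb = _pair_matrices(rng)
        ab = gdttc.call_edges(ea, eb, ea, eb)
        ba = gdttc.call_edges(eb, ea, eb, ea)
        assert ab.pair_set() == ba.pair_set()

    def test_small_donor_intersection_fatal(self, rng):
        ea, eb = _pair_matrices(rng, n_donors=12)
        eb = eb.subset_donors(eb.donors[:8])
        with pytest.raises(ValidationError, match="donors"):
            gdttc.call_edges(ea, eb, ea, eb)

    def test_gene_with_missing_value_dropped_for_the_pair(self, rng):
        ea, eb = _pair_matrices(rng)
        ea.data.iloc[0, 0] = np.nan
        edges = gdttc.call_edges(ea, eb, ea, eb)
        assert "G00" not in {r.gene_a for r in edges.records}
        assert edges.n_genes_a == 19


class TestPermutationFdr:
    def test_strong_signal_gives_small_fdr(self, rng):
        ea, eb = _pair_matrices(rng, n_genes=30, n_donors=60, planted=10, r=0.8)
        K = gdttc.KinshipMatrix(np.eye(60), [f"D{i}" for i in range(60)])
        res = gdttc.permutation_fdr(ea, eb, K, n_perm=3, seed=1)
        assert res.observed_edges >= 8
        assert res.fdr < 0.3

    def test_zero_observed_edges_reports_nan(self, rng):
        ea, eb = _pair_matrices(rng, n_genes=5, planted=0)
        K = gdttc.KinshipMatrix(np.eye(40), [f"D{i}" for i in range(40)])
        res = gdttc.permutation_fdr(ea, eb, K, n_perm=2, seed=0)
        assert res.observed_edges == 0 and np.isnan(res.fdr)

    def test_nonpositive_permutation_count_rejected(self, rng):
        ea, eb = _pair_matrices(rng)
        K = gdttc.KinshipMatrix(np.eye(40), [f"D{i}" for i in range(40)])
        with pytest.raises(ValueError):
            gdttc.permutation_fdr(ea, eb, K, n_perm=0, seed=0)
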