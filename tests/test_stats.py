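"""Validation statistics: rank-sum tests, BH, Pearson combination, QC,
enrichment fractions and Wasserstein distances, each against an independent
oracle where one exists."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from senset import stats


# ---------------------------------------------------------------------------
# oracles

def bh_brute_force(p):
    """Step-up definition: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def exact_u_pmf(n, m):
    """Distribution of the Mann-Whitney U statistic for tie-free samples,
    by exact enumeration of rank assignments (dynamic programming)."""
    # f[i][u]: number of ways to place i x-ranks among i+j seen so far with U=u
    f = np.zeros((n + 1, n * m + 1), dtype=float)
    f[0, 0] = 1.0
    for k in range(1, n + m + 1):
        new = np.zeros_like(f)
        for i in range(min(k, n), -1, -1):
            if k - i > m:
                continue
            # element k is either an x (adds j = k-1-(i-1) ... ) or a y
            if i > 0:
                u_add = k - i  # number of y's preceding this x
                new[i, u_add:] += f[i - 1, :n * m + 1 - u_add]
            if k - i <= m and k - i > 0:
                new[i, :] += f[i, :]
        f = new
    pmf = f[n] / f[n].sum()
    return pmf


def exact_two_sided_p(x, y):
    n, m = len(x), len(y)
    u = sps.mannwhitneyu(x, y, method="asymptotic").statistic
    pmf = exact_u_pmf(n, m)
    center = n * m / 2.0
    dev = abs(u - center)
    support = np.arange(n * m + 1)
    return pmf[np.abs(support - center) >= dev - 1e-12].sum()


# ---------------------------------------------------------------------------

class TestRankSum:
    def test_extreme_separation_small_sample_exact(self):
        _, p = stats.rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = stats.rank_sum_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_symmetry_in_sample_order(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=9)
        assert stats.rank_sum_test(x, y)[1] == pytest.approx(stats.rank_sum_test(y, x)[1])

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            m = int(rng.integers(3, 21 - n))
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            _, p = stats.rank_sum_test(x, y)
            assert p == pytest.approx(exact_two_sided_p(x, y), abs=1e-10)

    def test_normal_approximation_close_to_exact(self, rng):
        # the asymptotic path only runs at n+m > 20 (or with ties); verify it
        # stays close to the enumeration oracle around that switchover
        for _ in range(30):
            n = int(rng.integers(8, 14))
            m = int(rng.integers(max(8, 21 - n), 15))
            x, y = rng.normal(size=n), rng.normal(size=m)
            p_asym = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
            assert abs(p_asym - exact_two_sided_p(x, y)) <= 0.02

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            stats.rank_sum_test([], [1.0])

    def test_matrix_path_equals_scalar_path(self, rng):
        Xa = rng.normal(size=(30, 5))
        Xb = rng.normal(size=(25, 5))
        U, p, delta = stats.rank_sum_matrix(Xa, Xb)
        for j in range(5):
            u_j, p_j = stats.rank_sum_test(Xa[:, j], Xb[:, j])
            assert U[j] == pytest.approx(u_j) and p[j] == pytest.approx(p_j)
        assert np.allclose(delta, Xa.mean(0) - Xb.mean(0))


class TestBH:
    def test_worked_examples(self):
        assert np.allclose(stats.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(stats.bh_adjust([0.05, 1.0]), [0.10, 1.0])
        assert stats.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(stats.bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            stats.bh_adjust([-0.1])


class TestPearsonCombine:
    def test_single_p_is_recovered(self):
        assert stats.pearson_combine([0.05]).combined_p == pytest.approx(0.05, abs=1e-12)

    def test_half_worked_example(self):
        res = stats.pearson_combine([0.5])
        assert res.statistic == pytest.approx(-2 * np.log(0.5), abs=1e-4)
        assert res.combined_p == pytest.approx(0.5, abs=1e-12)

    def test_against_chi2_cdf_oracle(self, rng):
        res = stats.pearson_combine([0.1, 0.2, 0.3])
        P = -2 * (np.log(0.9) + np.log(0.8) + np.log(0.7))
        assert res.statistic == pytest.approx(P, abs=1e-12)
        assert res.df == 6
        assert res.combined_p == pytest.approx(sps.chi2.cdf(P, 6), abs=1e-10)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 20))) * 0.999
            res = stats.pearson_combine(p)
            oracle = sps.chi2.cdf(-2 * np.sum(np.log(1 - p)), 2 * p.size)
            assert res.combined_p == pytest.approx(oracle, abs=1e-10)

    def test_p_equal_one_is_degenerate(self):
        res = stats.pearson_combine([0.2, 1.0])
        assert res.degenerate and res.combined_p == 1.0 and np.isinf(res.statistic)

    def test_monotone_in_each_input(self, rng):
        base = np.array([0.1, 0.4, 0.7])
        p0 = stats.pearson_combine(base).combined_p
        for i in range(3):
            bumped = base.copy()
            bumped[i] += 0.05
            assert stats.pearson_combine(bumped).combined_p >= p0

    def test_null_combined_p_is_uniform(self, rng):
        combined = [stats.pearson_combine(rng.random(5)).combined_p for _ in range(2000)]
        assert sps.kstest(combined, "uniform").pvalue > 0.01


class TestQCFilter:
    @staticmethod
    def _toy(counts):
        return ad.AnnData(X=np.asarray(counts, dtype=float),
                          obs=pd.DataFrame(index=[f"c{i}" for i in range(len(counts))]))

    def test_cell_count_boundary(self):
        # 500 total counts and >=400 genes required; use scaled thresholds here
        X = np.zeros((2, 5))
        X[0] = [100, 100, 100, 100, 99]   # 499 -> removed
        X[1] = [100, 100, 100, 100, 100]  # 500 -> kept
        out = stats.qc_filter(self._toy(X), min_counts=500, min_genes=5, min_gene_counts=0)
        assert out.n_obs == 1 and out.obs_names[0] == "c1"

    def test_zero_thresholds_are_identity(self, rng):
        X = rng.poisson(2.0, size=(10, 8)).astype(float)
        out = stats.qc_filter(self._toy(X), min_counts=0, min_genes=0, min_gene_counts=0)
        assert out.shape == (10, 8)

    def test_matches_brute_force(self, rng):
        X = rng.poisson(3.0, size=(40, 25)).astype(float)
        a = self._toy(X)
        out = stats.qc_filter(a, min_counts=60, min_genes=15, min_gene_counts=80)
        keep_cells = (X.sum(1) >= 60) & ((X > 0).sum(1) >= 15)
        keep_genes = X[keep_cells].sum(0) >= 80
        assert np.allclose(np.asarray(out.X), X[np.ix_(keep_cells, keep_genes)])

    def test_cells_removed_before_genes(self):
        # a gene passing on all cells but failing after cell filtering must drop
        X = np.array([[0.0, 100.0], [500.0, 30.0], [500.0, 30.0]])
        out = stats.qc_filter(self._toy(X), min_counts=400, min_genes=1, min_gene_counts=100)
        assert out.n_vars == 1


class TestWasserstein:
    @staticmethod
    def _cohort(xa, xb):
        X = np.concatenate([xa, xb])[:, None].astype(float)
        obs = pd.DataFrame({"cell_type": ["t"] * len(X)},
                           index=[f"c{i}" for i in range(len(X))])
        a = ad.AnnData(X=X, obs=obs)
        mask_a = np.arange(len(X)) < len(xa)
        return a, mask_a, ~mask_a

    def test_identical_samples_give_zero(self):
        a, ma, mb = self._cohort([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stats.wasserstein_shift(a, ma, mb)["t"] == 0.0

    def test_point_masses(self):
        a, ma, mb = self._cohort([2.5, 2.5], [4.0, 4.0])
        assert stats.wasserstein_shift(a, ma, mb)["t"] == pytest.approx(1.5)

    def test_quantile_integral_example(self):
        a, ma, mb = self._cohort([0.0, 1.0], [0.0, 0.0])
        assert stats.wasserstein_shift(a, ma, mb)["t"] == pytest.approx(0.5)

    def test_metric_properties(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(1.0, 2.0, size=60)
        z = rng.exponential(size=40)
        d = sps.wasserstein_distance
        assert d(x, y) == pytest.approx(d(y, x))
        assert d(x, z) <= d(x, y) + d(y, z) + 1e-12
        c = 3.7
        assert d(c * x, c * y) == pytest.approx(abs(c) * d(x, y))

    def test_subsampling_is_seeded(self, rng):
        xa, xb = rng.normal(size=300), rng.normal(0.5, 1, size=300)
        a, ma, mb = self._cohort(xa, xb)
        d1 = stats.wasserstein_shift(a, ma, mb, max_cells=100, seed=7)
        d2 = stats.wasserstein_shift(a, ma, mb, max_cells=100, seed=7)
        assert d1.equals(d2)


class TestEnrichment:
    @staticmethod
    def _two_group_cohort(rng, n=120, n_genes=30, shift_genes=(), shift=1.0):
        X = rng.normal(size=(2 * n, n_genes))
        for g in shift_genes:
            X[:n, g] += shift
        genes = [f"G{i}" for i in range(n_genes)]
        obs = pd.DataFrame({"cell_type": ["t"] * (2 * n)},
                           index=[f"c{i}" for i in range(2 * n)])
        a = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
        mask_a = np.arange(2 * n) < n
        return a, mask_a, genes

    def test_planted_all_up_set_recovered(self, rng):
        a, mask_a, genes = self._two_group_cohort(rng, shift_genes=range(10))
        res = stats.geneset_enrichment(a, genes[:10], mask_a, ~mask_a)
        assert res.frac_up == 1.0 and res.frac_down == 0.0

    def test_permuted_labels_calibrated(self, rng):
        a, mask_a, genes = self._two_group_cohort(rng, n=200, n_genes=200)
        perm = rng.permutation(mask_a)
        res = stats.geneset_enrichment(a, genes, perm, ~perm)
        assert res.frac_up + res.frac_down <= 0.05  # BH at FDR 0.05 under the null

    def test_single_gene_fraction_is_binary(self, rng):
        a, mask_a, genes = self._two_group_cohort(rng, shift_genes=[0])
        res = stats.geneset_enrichment(a, [genes[0]], mask_a, ~mask_a)
        assert res.frac_up in (0.0, 1.0)

    def test_single_gene_combined_reduces_to_own_test(self, rng):
        n = 60
        X = rng.normal(size=(2 * n, 3))
        obs = pd.DataFrame({"cell_type": ["t"] * (2 * n),
                            "condition": ["treated"] * n + ["control"] * n},
                           index=[f"c{i}" for i in range(2 * n)])
        a = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(["A", "B", "C"], name="gene")))
        table = stats.celltype_combined_enrichment(a, {"solo": ["A"]})
        _, p = stats.rank_sum_test(X[:n, 0], X[n:, 0])
        assert table.iloc[0]["combined_p"] == pytest.approx(p, abs=1e-12)
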