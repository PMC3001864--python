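"""Co-expression network: soft thresholding, TOM, modules, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossqtl.network import (NetworkConfig, adjacency, cluster_modules,
                              connectivity, ko_signature, module_eigengene,
                              pick_beta, scale_free_r2, select_top_variable,
                              set_enrichment, tom)
from crossqtl.sim import simulate_modular_expression as \
    planted_module_expression


def test_modular_generator_has_planted_correlation_structure():
    expr, labels = planted_module_expression(
        n_modules=2, module_size=20, n_noise=10, n_individuals=4000,
        within_r=0.6, seed=99)
    mat = expr.to_numpy()
    corr = np.corrcoef(mat)
    within = corr[:20, :20][np.triu_indices(20, k=1)]
    between = corr[:20, 20:40].ravel()
    assert within.mean() == pytest.approx(0.6, abs=0.03)
    assert abs(between.mean()) < 0.03


class TestSelectTopVariable:
    def test_direct_ranking(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            [rng.normal(0, s, 100) for s in (2.0, 1.7, 1.4, 1.0)],
            index=["a", "b", "c", "d"])
        assert list(select_top_variable(expr, 0.5)) == ["a", "b"]

    def test_fraction_one_keeps_all(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(7, 20)))
        assert len(select_top_variable(expr, 1.0)) == 7

    def test_count_uses_floor(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(10, 20)))
        assert len(select_top_variable(expr, 0.25)) == 2

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_top_variable(pd.DataFrame(np.zeros((2, 2))), 0.0)


class TestAdjacency:
    def test_beta_one_is_absolute_correlation(self):
        r = np.array([[1.0, -0.4], [-0.4, 1.0]])
        a = adjacency(r, 1)
        assert a[0, 1] == pytest.approx(0.4)
        assert a[0, 0] == 0.0

    def test_powers(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert adjacency(r, 6)[0, 1] == pytest.approx(0.015625)
        assert adjacency(np.zeros((2, 2)), 3)[0, 1] == 0.0

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency(np.eye(2), 0)

    def test_monotone_decreasing_in_beta(self):
        rng = np.random.default_rng(3)
        r = np.clip(rng.uniform(-0.9, 0.9, (5, 5)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        prev = adjacency(r, 1)
        for beta in (2, 4, 8):
            cur = adjacency(r, beta)
            assert (cur <= prev + 1e-12).all()
            prev = cur


class TestScaleFreeR2:
    def test_exact_power_law_histogram_is_linear(self):
        # bin centres 4^j with counts 8^(5-j): p(k) proportional to k^-1.5
        ks = np.concatenate([
            np.full(8 ** (5 - j), 4.0 ** j) for j in range(6)])
        r2, degenerate = scale_free_r2(ks, n_bins=6)
        assert not degenerate
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_connectivity_is_degenerate(self):
        r2, degenerate = scale_free_r2(np.full(100, 3.0), n_bins=10)
        assert degenerate
        assert r2 == 0.0

    def test_matches_direct_regression_oracle(self):
        rng = np.random.default_rng(4)
        k = rng.lognormal(1.0, 0.6, size=2000)
        n_bins = 10
        r2, _ = scale_free_r2(k, n_bins=n_bins)
        # independent binning + regression
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
        xs = [logk[which == b].mean() for b in range(n_bins)
              if (which == b).any()]
        ys = [np.log10((which == b).mean()) for b in range(n_bins)
              if (which == b).any()]
        slope, intercept, r, _, _ = stats.linregress(xs, ys)
        assert r2 == pytest.approx(r ** 2, abs=1e-12)

    def test_invariant_to_scaling_connectivity(self):
        rng = np.random.default_rng(5)
        k = rng.lognormal(0.5, 0.7, size=500)
        a, _ = scale_free_r2(k)
        b, _ = scale_free_r2(10.0 * k)
        assert a == pytest.approx(b, abs=1e-9)


class TestPickBeta:
    def test_zero_threshold_returns_smallest_candidate(self):
        expr, _ = planted_module_expression(n_modules=3, module_size=10,
                                            n_noise=10, n_individuals=50)
        corr = np.corrcoef(expr.to_numpy())
        cfg = NetworkConfig(scale_free_r2_min=0.0,
                            beta_candidates=(2, 3, 4))
        beta, diag = pick_beta(corr, cfg)
        assert beta == 2

    def test_returns_first_candidate_crossing_threshold(self):
        expr, _ = planted_module_expression(seed=6)
        corr = np.corrcoef(expr.to_numpy())
        cfg = NetworkConfig()
        beta, diag = pick_beta(corr, cfg)
        crossing = diag[diag["r2"] > cfg.scale_free_r2_min]["beta"]
        if len(crossing):
            assert beta == crossing.iloc[0]

    def test_warns_when_no_candidate_crosses(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 30))
        corr = np.corrcoef(x)
        cfg = NetworkConfig(scale_free_r2_min=0.9999,
                            beta_candidates=(1, 2))
        with pytest.warns(UserWarning, match="argmax"):
            pick_beta(corr, cfg)


def tom_oracle(a):
    """Triple-loop topological overlap."""
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTom:
    def test_zero_adjacency(self):
        omega = tom(np.zeros((4, 4)))
        assert np.allclose(omega, np.eye(4))

    def test_complete_graph_has_unit_overlap(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        omega = tom(a)
        assert np.allclose(omega, 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        assert np.allclose(tom(a), tom_oracle(a), atol=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.uniform(0, 1, (12, 12))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            omega = tom(a)
            assert np.allclose(omega, omega.T, atol=1e-12)
            assert omega.min() >= -1e-12
            assert omega.max() <= 1 + 1e-12

    def test_out_of_range_adjacency_rejected(self):
        with pytest.raises(ValueError):
            tom(np.full((3, 3), 1.5))


class TestClusterModules:
    def _tom_of(self, expr, beta=6):
        corr = np.corrcoef(expr.to_numpy())
        return tom(adjacency(corr, beta))

    def test_two_perfect_blocks_recovered(self):
        expr, truth = planted_module_expression(
            n_modules=2, module_size=30, n_noise=0, n_individuals=300,
            within_r=0.9, seed=10)
        cfg = NetworkConfig(min_module_size=20)
        part = cluster_modules(self._tom_of(expr), expr.index, cfg)
        assert len(part.modules) == 2
        for m in range(2):
            members = part.labels.iloc[m * 30:(m + 1) * 30]
            assert members.nunique() == 1
            assert members.iloc[0] != "grey"

    def test_planted_modules_recovered_with_noise(self):
        from sklearn.metrics import adjusted_rand_score
        expr, truth = planted_module_expression(seed=11)
        cfg = NetworkConfig(min_module_size=20)
        part = cluster_modules(self._tom_of(expr), expr.index, cfg)
        planted = truth >= 0
        pred = part.labels.to_numpy()
        ari = adjusted_rand_score(truth[planted], pred[planted])
        assert ari > 0.8
        assert (pred[~planted] == "grey").mean() >= 0.8

    def test_too_few_genes_all_grey(self):
        cfg = NetworkConfig(min_module_size=20)
        omega = np.eye(5)
        with pytest.warns(UserWarning):
            part = cluster_modules(omega, [f"g{i}" for i in range(5)], cfg)
        assert (part.labels == "grey").all()

    def test_colors_assigned_by_descending_size(self):
        expr, _ = planted_module_expression(
            n_modules=2, module_size=30, n_noise=0, n_individuals=300,
            within_r=0.9, seed=12)
        # make the second block larger
        expr2, _ = planted_module_expression(
            n_modules=1, module_size=50, n_noise=0, n_individuals=300,
            within_r=0.9, seed=13)
        expr2.index = [f"h{i}" for i in range(len(expr2))]
        both = pd.concat([expr.iloc[:30], expr2])
        part = cluster_modules(self._tom_of(both), both.index,
                               NetworkConfig(min_module_size=20))
        sizes = part.sizes.drop(index="grey", errors="ignore")
        assert sizes.index[0] == "turquoise"
        assert sizes.iloc[0] == max(sizes)


class TestModuleEigengene:
    def test_rank_one_module_recovers_factor(self):
        rng = np.random.default_rng(14)
        factor = rng.normal(size=100)
        expr = pd.DataFrame(np.outer([1.0, 2.0, -1.5], factor),
                            index=["a", "b", "c"])
        eig = module_eigengene(expr, ["a", "b", "c"])
        assert abs(np.corrcoef(eig, factor)[0, 1]) == pytest.approx(
            1.0, abs=1e-9)

    def test_sign_flip_flips_score(self):
        rng = np.random.default_rng(15)
        expr = pd.DataFrame(rng.normal(size=(5, 60)),
                            index=list("abcde"))
        a = module_eigengene(expr, list("abcde"))
        b = module_eigengene(-expr, list("abcde"))
        assert np.allclose(a, -b, atol=1e-9)

    def test_dominant_factor_tracked(self):
        rng = np.random.default_rng(16)
        f1 = rng.normal(size=150)
        f2 = rng.normal(size=150)
        rows = [2.0 * f1 + 0.3 * f2 + rng.normal(0, 0.3, 150)
                for _ in range(10)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(10)])
        eig = module_eigengene(expr, expr.index)
        assert abs(np.corrcoef(eig, f1)[0, 1]) > 0.9


def hypergeom_upper_tail_oracle(overlap, universe, set_size, module_size):
    total = 0.0
    for k in range(overlap, min(set_size, module_size) + 1):
        total += (math.comb(set_size, k)
                  * math.comb(universe - set_size, module_size - k)
                  / math.comb(universe, module_size))
    return total


class TestSetEnrichment:
    def test_set_equal_to_module(self):
        universe = [f"g{i}" for i in range(100)]
        fold, p = set_enrichment(universe[:10], universe[:10], universe)
        assert fold == pytest.approx(10.0)  # |U| / |set|

    def test_disjoint_set_and_module(self):
        universe = [f"g{i}" for i in range(100)]
        fold, p = set_enrichment(universe[:10], universe[10:30], universe)
        assert fold == 0.0
        assert p >= 0.5

    def test_p_matches_exhaustive_hypergeometric_sum(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:10]
        module = universe[5:25]  # overlap 5
        fold, p = set_enrichment(gene_set, module, universe)
        assert p == pytest.approx(
            hypergeom_upper_tail_oracle(5, 100, 10, 20), abs=1e-12)
        assert fold == pytest.approx((5 / 20) / (10 / 100))

    def test_empty_inputs(self):
        universe = ["a", "b", "c"]
        fold, p = set_enrichment([], ["a"], universe)
        assert math.isnan(fold)
        assert p == 1.0


class TestKoSignature:
    def test_identical_groups_give_empty_signature(self):
        rng = np.random.default_rng(17)
        base = pd.DataFrame(rng.normal(size=(50, 3)),
                            index=[f"g{i}" for i in range(50)])
        sig, table = ko_signature(base, base.copy())
        assert len(sig) == 0
        assert (table["p"] > 0.999).all()

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(18)
        n_genes = 2000
        wt = pd.DataFrame(rng.normal(size=(n_genes, 3)),
                          index=[f"g{i}" for i in range(n_genes)])
        ko = pd.DataFrame(rng.normal(size=(n_genes, 3)), index=wt.index)
        ko.iloc[:50] += 5.0  # 5-sigma shift in the first 50 genes
        sig, _ = ko_signature(ko, wt, alpha=0.05)
        recovered = sum(g in sig for g in wt.index[:50])
        assert recovered >= 45

    def test_null_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(19)
        n_genes = 2000
        a = pd.DataFrame(rng.normal(size=(n_genes, 4)),
                         index=[f"g{i}" for i in range(n_genes)])
        b = pd.DataFrame(rng.normal(size=(n_genes, 4)), index=a.index)
        sig, _ = ko_signature(a, b, alpha=0.05)
        rate = len(sig) / n_genes
        se = math.sqrt(0.05 * 0.95 / n_genes)
        assert abs(rate - 0.05) < 2.5 * se

    def test_single_sample_groups_rejected(self):
        df = pd.DataFrame(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            ko_signature(df, df)
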