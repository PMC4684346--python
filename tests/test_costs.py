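"""Node costs (SSE, Mahalanobis, copula) and the exhaustive split search."""

import itertools

import numpy as np
import pytest

from copulaforest import (
    Dataset,
    best_split,
    cost_copula,
    cost_mahalanobis,
    cost_sse,
    empirical_copula,
    enumerate_split_candidates,
    make_criterion,
    node_cost,
)
from copulaforest.costs import MIN_COPULA_NODE


def brute_force_best_split(ds, rows, features, crit):
    """Independent oracle: try every (feature, threshold) pair with direct
    per-child cost evaluation; same tie rule (feature asc, threshold asc)."""
    rows = np.asarray(rows)
    parent = node_cost(ds.Y[rows], crit)
    best = None
    for f in sorted(features):
        for z in sorted(set(ds.X[rows, f])):
            left = rows[ds.X[rows, f] <= z]
            right = rows[ds.X[rows, f] > z]
            if len(left) == 0 or len(right) == 0:
                continue
            gain = parent - node_cost(ds.Y[left], crit) - node_cost(ds.Y[right], crit)
            if best is None or gain > best[0] + 1e-9 * (1.0 + abs(best[0])):
                best = (gain, f, z)
    return best


class TestCostSSE:
    def test_zero_for_constant_and_singleton(self):
        assert cost_sse([3.0, 3.0, 3.0]) == 0.0
        assert cost_sse([7.0]) == 0.0

    def test_hand_computed(self):
        assert cost_sse([1.0, 2.0, 3.0]) == pytest.approx(2.0)


class TestCostMahalanobis:
    def test_identity_precision_equals_columnwise_sse(self, rng):
        Y = rng.normal(size=(12, 2))
        crit = make_criterion("mahalanobis", Y)
        crit.lambda_inv = np.eye(2)
        assert cost_mahalanobis(Y, crit) == pytest.approx(
            cost_sse(Y[:, 0]) + cost_sse(Y[:, 1])
        )

    def test_univariate_reduces_to_scaled_sse(self, rng):
        y = rng.normal(size=(15, 1))
        crit = make_criterion("mahalanobis", y)
        sigma2 = np.var(y, ddof=1)
        assert cost_mahalanobis(y, crit) == pytest.approx(cost_sse(y) / sigma2, rel=1e-6)

    def test_two_point_quadratic_form_by_hand(self):
        # points symmetric about the mean: deviations (+d, -d)
        rho = 0.5
        crit = make_criterion("mahalanobis", np.random.default_rng(0).normal(size=(5, 2)))
        crit.lambda_inv = np.linalg.inv(np.array([[1.0, rho], [rho, 1.0]]))
        Y = np.array([[1.0, 2.0], [3.0, 0.0]])
        d = np.array([-1.0, 1.0])
        expected = 2 * d @ crit.lambda_inv @ d
        assert cost_mahalanobis(Y, crit) == pytest.approx(expected)

    def test_nonnegative(self, rng):
        Y = rng.normal(size=(20, 3))
        crit = make_criterion("mahalanobis", Y)
        assert cost_mahalanobis(Y, crit) >= 0


class TestCostCopula:
    def test_full_training_set_has_zero_d1(self, rng):
        Y = rng.normal(size=(30, 2))
        crit = make_criterion("copula", Y)
        dc, d1, d2 = cost_copula(Y, crit)
        assert d1 == 0.0
        assert dc == pytest.approx(crit.alpha * d2)

    def test_d1_bounded_by_node_size_bivariate(self, rng):
        Y = rng.normal(size=(40, 2))
        crit = make_criterion("copula", Y)
        for _ in range(20):
            sub = Y[rng.choice(40, size=rng.integers(3, 20), replace=False)]
            _, d1, _ = cost_copula(sub, crit)
            assert d1 <= len(sub) * 1.1  # 6 * Psi <= 1 up to empirical slack

    def test_matches_bruteforce_on_small_fixture(self):
        root = np.array([[0.0, 1.0], [1.0, 3.0], [2.0, 0.0], [3.0, 2.0],
                         [4.0, 5.0], [5.0, 4.0]])
        node = root[[0, 2, 3, 5]]
        K = 4
        crit = make_criterion("copula", root, alpha=1.0, grid_resolution=K)
        dc, d1, d2 = cost_copula(node, crit)
        # brute force: Psi over the K x K lattice, column SSE over sigma^2
        cn = empirical_copula(node, K).grid_values
        cr = empirical_copula(root, K).grid_values
        psi = np.abs(cn - cr).sum() / K**2
        assert d1 == pytest.approx(6 * 4 * psi)
        sig = root.var(axis=0)
        assert d2 == pytest.approx(cost_sse(node[:, 0]) / sig[0] + cost_sse(node[:, 1]) / sig[1])
        assert dc == pytest.approx(d1 + d2)

    def test_tiny_and_univariate_nodes_have_zero_d1(self, rng):
        Y = rng.normal(size=(20, 2))
        crit = make_criterion("copula", Y)
        _, d1, _ = cost_copula(Y[: MIN_COPULA_NODE - 1], crit)
        assert d1 == 0.0
        y1 = rng.normal(size=(20, 1))
        crit1 = make_criterion("copula", y1)
        _, d1, _ = cost_copula(y1[:5], crit1)
        assert d1 == 0.0

    def test_per_column_missing_values_tolerated(self, rng):
        Y = rng.normal(size=(20, 2))
        crit = make_criterion("copula", Y)
        Yn = Y[:8].copy()
        Yn[0, 1] = np.nan
        dc, d1, d2 = cost_copula(Yn, crit)
        # D2 sums observed entries; Psi uses the 7 complete rows
        exp_d2 = cost_sse(Yn[:, 0]) / crit.root_sigma2[0] + cost_sse(Yn[1:, 1]) / crit.root_sigma2[1]
        assert d2 == pytest.approx(exp_d2)
        _, d1_complete, _ = cost_copula(Yn[1:], crit)
        assert d1 == pytest.approx(d1_complete)

    def test_monte_carlo_mode_above_three_dimensions(self, rng):
        Y = rng.normal(size=(25, 4))
        crit = make_criterion("copula", Y, mc_dim_threshold=3)
        assert crit.mc_points is not None
        dc, d1, d2 = cost_copula(Y[:10], crit)
        assert d1 > 0 and d2 > 0
        assert cost_copula(Y, crit)[1] == pytest.approx(0.0, abs=1e-12)


class TestBestSplit:
    def test_perfect_separation_hand_enumerated(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        Y = np.array([[0.0], [0.0], [10.0], [10.0]])
        ds = Dataset(list("abcd"), X, Y)
        crit = make_criterion("sse", Y)
        cand = best_split(ds, [0, 1, 2, 3], [0], crit)
        # parent SSE = sum (y - 5)^2 = 100; both children pure
        assert cand.gain == pytest.approx(100.0)
        assert 2.0 <= cand.threshold < 3.0
        assert sorted(cand.left_rows) == [0, 1]

    def test_constant_feature_yields_none(self, rng):
        ds = Dataset(list("abc"), np.ones((3, 1)), rng.normal(size=(3, 1)))
        assert best_split(ds, [0, 1, 2], [0], make_criterion("sse", ds.Y)) is None

    @pytest.mark.parametrize("kind", ["sse", "mahalanobis", "copula"])
    def test_oracle_equivalence_random_fixtures(self, kind, rng):
        for trial in range(12):
            n = int(rng.integers(5, 25))
            M = int(rng.integers(1, 5))
            r = int(rng.integers(1, 4)) if kind != "sse" else 1
            X = np.round(rng.normal(size=(n, M)), 1)  # rounding forces ties
            Y = rng.normal(size=(n, r))
            ds = Dataset([str(i) for i in range(n)], X, Y)
            crit = make_criterion(kind, Y, grid_resolution=5)
            rows = rng.choice(n, size=int(rng.integers(3, n + 1)), replace=True)
            got = best_split(ds, rows, range(M), crit)
            want = brute_force_best_split(ds, rows, range(M), crit)
            if want is None:
                assert got is None
                continue
            assert got.feature == want[1]
            assert got.threshold == pytest.approx(want[2])
            assert got.gain == pytest.approx(want[0], abs=1e-9)

    @pytest.mark.parametrize("kind", ["sse", "mahalanobis"])
    def test_variance_decomposition_gains_nonnegative(self, kind, rng):
        Y = rng.normal(size=(20, 2)) if kind == "mahalanobis" else rng.normal(size=(20, 1))
        ds = Dataset([str(i) for i in range(20)], rng.normal(size=(20, 3)), Y)
        crit = make_criterion(kind, Y)
        for c in enumerate_split_candidates(ds, range(20), range(3), crit):
            assert c.gain >= -1e-9

    def test_invariant_to_row_order_and_unused_feature_transforms(self, rng):
        X = rng.normal(size=(15, 3))
        Y = rng.normal(size=(15, 2))
        ds = Dataset([str(i) for i in range(15)], X, Y)
        crit = make_criterion("copula", Y, grid_resolution=6)
        rows = np.arange(15)
        a = best_split(ds, rows, [0, 1, 2], crit)
        b = best_split(ds, rng.permutation(rows), [0, 1, 2], crit)
        assert (a.feature, a.threshold, a.gain) == (b.feature, b.threshold, pytest.approx(a.gain))
        X2 = X.copy()
        unused = 3 - a.feature if a.feature in (0, 1) else 0
        X2[:, unused] = np.exp(X2[:, unused])  # strictly increasing
        ds2 = Dataset(ds.sample_ids, X2, Y)
        c = best_split(ds2, rows, [0, 1, 2], crit)
        assert c.feature == a.feature and c.gain == pytest.approx(a.gain)

    def test_deterministic_on_repeat(self, tiny_ds):
        crit = make_criterion("copula", tiny_ds.Y, grid_resolution=5)
        a = best_split(tiny_ds, range(8), [0, 1, 2], crit)
        b = best_split(tiny_ds, range(8), [0, 1, 2], crit)
        assert (a.feature, a.threshold, a.gain) == (b.feature, b.threshold, b.gain)

    def test_min_child_filters_small_leaves(self, rng):
        X = rng.normal(size=(12, 2))
        Y = rng.normal(size=(12, 2))
        ds = Dataset([str(i) for i in range(12)], X, Y)
        crit = make_criterion("sse", Y)
        for c in enumerate_split_candidates(ds, range(12), [0, 1], crit, min_child=4):
            assert len(c.left_rows) >= 4 and len(c.right_rows) >= 4

    def test_univariate_copula_orders_like_sse(self, rng):
        # with r = 1 the copula term vanishes, so split ordering matches SSE
        X = rng.normal(size=(18, 3))
        y = rng.normal(size=(18, 1))
        ds = Dataset([str(i) for i in range(18)], X, y)
        c_sse = make_criterion("sse", y)
        c_cop = make_criterion("copula", y, alpha=2.7)
        a = best_split(ds, range(18), range(3), c_sse)
        b = best_split(ds, range(18), range(3), c_cop)
        assert (a.feature, a.threshold) == (b.feature, b.threshold)

    def test_copula_candidates_record_child_d1_d2(self, rng):
        Y = rng.normal(size=(10, 2))
        ds = Dataset([str(i) for i in range(10)], rng.normal(size=(10, 2)), Y)
        crit = make_criterion("copula", Y, grid_resolution=5)
        cands = enumerate_split_candidates(ds, range(10), [0, 1], crit)
        assert cands
        for c in cands:
            for v in (c.d1_left, c.d2_left, c.d1_right, c.d2_right):
                assert v is not None and v >= 0
            dcL, d1L, d2L = cost_copula(ds.Y[c.left_rows], crit)
            assert c.d1_left == pytest.approx(d1L) and c.d2_left == pytest.approx(d2L)
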