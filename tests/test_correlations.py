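"""Polychoric/polyserial estimators, dispatch, and PD repair."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import sympnet as sn
from sympnet.correlations import EstimationError


def expand_table(table):
    """Turn a contingency table of counts into paired ordinal columns."""
    xs, ys = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            xs += [i] * int(count)
            ys += [j] * int(count)
    return np.array(xs, float), np.array(ys, float)


def grid_search_polychoric(table, tol=1e-6):
    """Independent oracle: coarse-to-fine likelihood grid search using
    scipy's generic MVN CDF for the rectangle probabilities."""
    x, y = expand_table(table)
    tau_x = norm.ppf(np.cumsum(np.bincount(x.astype(int)))[:-1] / x.size)
    tau_y = norm.ppf(np.cumsum(np.bincount(y.astype(int)))[:-1] / y.size)
    cuts_x = np.concatenate([[-np.inf], tau_x, [np.inf]])
    cuts_y = np.concatenate([[-np.inf], tau_y, [np.inf]])
    tab = np.asarray(table, float)

    def F(h, k, rho):
        if h == -np.inf or k == -np.inf:
            return 0.0
        if h == np.inf and k == np.inf:
            return 1.0
        if h == np.inf:
            return norm.cdf(k)
        if k == np.inf:
            return norm.cdf(h)
        return float(multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k]))

    def nll(rho):
        total = 0.0
        for i in range(tab.shape[0]):
            for j in range(tab.shape[1]):
                p = (F(cuts_x[i + 1], cuts_y[j + 1], rho) - F(cuts_x[i], cuts_y[j + 1], rho)
                     - F(cuts_x[i + 1], cuts_y[j], rho) + F(cuts_x[i], cuts_y[j], rho))
                total -= tab[i, j] * np.log(max(p, 1e-300))
        return total

    lo, hi = -0.999, 0.999
    for _ in range(4):  # each pass shrinks the bracket ~20x
        grid = np.linspace(lo, hi, 41)
        vals = [nll(r) for r in grid]
        k = int(np.argmin(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 40)]
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class TestThresholds:
    def test_equal_split_gives_zero_threshold(self):
        col = np.array([0] * 50 + [1] * 50, float)
        assert sn.estimate_thresholds(col) == pytest.approx([0.0], abs=1e-12)

    def test_symmetric_three_categories(self):
        col = np.repeat([0, 1, 2], [25, 50, 25]).astype(float)
        thr = sn.estimate_thresholds(col)
        assert thr[0] == pytest.approx(norm.ppf(0.25))
        assert thr[1] == pytest.approx(-thr[0])

    def test_normal_table_value(self):
        # 15.87% below the cut puts the threshold one SD below the mean
        col = np.repeat([0, 1], [1587, 8413]).astype(float)
        assert sn.estimate_thresholds(col)[0] == pytest.approx(-1.0, abs=1e-3)

    def test_constant_column_raises_with_item_name(self):
        with pytest.raises(EstimationError, match="cesd9"):
            sn.estimate_thresholds(np.zeros(20), name="cesd9")


class TestPolychoric:
    def test_independence_table_gives_zero(self):
        x, y = expand_table(np.outer([30, 50, 20], [40, 60]) // 10)
        assert sn.polychoric_pair(x, y) == pytest.approx(0.0, abs=1e-3)

    def test_perfect_association_hits_upper_bound(self):
        x, y = expand_table([[50, 0], [0, 50]])
        assert sn.polychoric_pair(x, y) == pytest.approx(0.999, abs=1e-9)

    @pytest.mark.parametrize("table", [
        [[40, 10], [10, 40]],
        [[30, 20], [15, 35]],
        [[10, 30], [35, 25]],
    ])
    def test_matches_grid_search_oracle(self, table):
        x, y = expand_table(table)
        assert sn.polychoric_pair(x, y) == pytest.approx(
            grid_search_polychoric(table), abs=1e-4)

    def test_symmetry_in_arguments(self):
        x, y = expand_table([[25, 10, 5], [10, 30, 10], [5, 15, 40]])
        assert sn.polychoric_pair(x, y) == pytest.approx(sn.polychoric_pair(y, x), abs=1e-9)

    def test_invariant_to_order_preserving_relabeling(self):
        x, y = expand_table([[25, 10, 5], [10, 30, 10], [5, 15, 40]])
        x2 = np.array([0, 5, 7], float)[x.astype(int)]
        assert sn.polychoric_pair(x, y) == pytest.approx(sn.polychoric_pair(x2, y), abs=1e-9)

    def test_too_few_pairwise_cases_raise(self):
        with pytest.raises(EstimationError, match="pairwise-complete"):
            sn.polychoric_pair(np.array([0.0, 1.0]), np.array([1.0, 0.0]))


class TestPolyserial:
    def test_deterministic_link_approaches_bound(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(3000)
        y = (x > np.median(x)).astype(float)
        assert sn.polyserial_pair(x, y) > 0.99

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        y = rng.integers(0, 3, 10_000).astype(float)
        assert abs(sn.polyserial_pair(x, y)) < 0.05

    def test_recovers_latent_correlation(self):
        rng = np.random.default_rng(2)
        n, rho = 20_000, 0.6
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        y = np.digitize(z[:, 1], [-0.6, 0.7]).astype(float)
        assert sn.polyserial_pair(z[:, 0], y) == pytest.approx(rho, abs=0.03)

    def test_zero_variance_continuous_raises(self):
        with pytest.raises(EstimationError, match="zero variance"):
            sn.polyserial_pair(np.ones(50), np.tile([0.0, 1.0], 25))


class TestCorrelationMatrix:
    def test_all_continuous_matches_product_moment(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 4))
        ds = sn.OrdinalDataset(values=X, item_codes=list("abcd"),
                               item_kind=["continuous"] * 4)
        R = sn.correlation_matrix(ds).R
        assert np.allclose(R, np.corrcoef(X.T), atol=1e-12)

    def test_output_is_symmetric_with_unit_diagonal(self, small_wave):
        _, ds = small_wave
        R = sn.correlation_matrix(ds).R
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)

    def test_round_trip_recovers_latent_correlations(self):
        model = sn.make_true_network(4, edge_prob=0.7, weight_range=(0.25, 0.4), seed=13)
        ds = sn.sample_ordinal_wave(model, 20_000, seed=14)
        R = sn.correlation_matrix(ds).R
        assert np.max(np.abs(R - model.latent_correlation())) <= 0.03

    def test_mixed_kinds_dispatch_and_pairwise_missingness(self):
        rng = np.random.default_rng(5)
        n = 600
        z = rng.multivariate_normal(np.zeros(3), np.full((3, 3), 0.5) + 0.5 * np.eye(3), n)
        vals = np.column_stack([
            np.digitize(z[:, 0], [-0.5, 0.5]).astype(float),
            z[:, 1],
            (z[:, 2] > 0).astype(float),
        ])
        vals[rng.random((n, 3)) < 0.1] = np.nan
        ds = sn.OrdinalDataset(values=vals, item_codes=["ord", "cont", "bin"],
                               item_kind=["ordinal", "continuous", "binary"])
        cm = sn.correlation_matrix(ds, pairwise_complete=True)
        assert cm.n_pairwise[0, 1] < n
        assert np.all(np.abs(cm.R[np.triu_indices(3, 1)] - 0.5) < 0.12)
        assert np.linalg.eigvalsh(cm.R).min() >= 0


class TestPDRepair:
    def test_pd_input_unchanged(self):
        R = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        assert np.allclose(sn.nearest_pd_repair(R), R, atol=1e-12)

    def test_indefinite_input_becomes_pd(self):
        R = np.full((3, 3), 0.9)
        np.fill_diagonal(R, 1.0)
        R[0, 2] = R[2, 0] = -0.9
        assert np.linalg.eigvalsh(R).min() < 0
        out = sn.nearest_pd_repair(R)
        assert np.linalg.eigvalsh(out).min() > 0
        assert np.allclose(np.diag(out), 1.0)

    def test_identity_fixed_point(self):
        assert np.allclose(sn.nearest_pd_repair(np.eye(4)), np.eye(4))

    def test_idempotent(self):
        R = np.full((3, 3), 0.9)
        np.fill_diagonal(R, 1.0)
        R[0, 2] = R[2, 0] = -0.9
        once = sn.nearest_pd_repair(R)
        assert np.allclose(sn.nearest_pd_repair(once), once, atol=1e-10)
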