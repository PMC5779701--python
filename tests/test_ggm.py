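"""Graphical-lasso fits, EBIC selection, and the partial-correlation identity."""

import numpy as np
import pytest
from scipy.optimize import minimize

import sympnet as sn
from sympnet.ggm import EDGE_EPS, ebic, glasso_fit, lambda_path


def direct_glasso_oracle(R, lam, x0=None):
    """Independent oracle: minimise the penalised negative log-likelihood
    over PD matrices via a Cholesky parametrisation and BFGS."""
    p = R.shape[0]
    tril = np.tril_indices(p)

    def unpack(v):
        L = np.zeros((p, p))
        L[tril] = v
        return L @ L.T

    def obj(v):
        T = unpack(v)
        sign, logdet = np.linalg.slogdet(T)
        if sign <= 0:
            return 1e12
        off = np.sum(np.abs(T)) - np.sum(np.abs(np.diag(T)))
        return float(np.sum(R * T) - logdet + lam * off)

    if x0 is None:
        x0 = np.eye(p)[tril]
    best = None
    for scale in (1.0, 0.5, 2.0):
        res = minimize(obj, x0 * scale, method="Nelder-Mead",
                       options={"maxiter": 100_000, "xatol": 1e-10, "fatol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    return unpack(best.x), best.fun


class TestGlassoFit:
    def test_large_penalty_empties_the_model(self):
        R = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]])
        Theta = glasso_fit(R, 0.5)
        W = sn.precision_to_pcor(Theta)
        assert np.max(np.abs(W)) < 1e-6

    def test_zero_penalty_inverts_the_correlation(self):
        R = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.3], [0.1, 0.3, 1.0]])
        assert np.allclose(glasso_fit(R, 0.0), np.linalg.inv(R), atol=1e-6)

    def test_two_node_soft_threshold_identity(self):
        """For p=2 the penalised solution's implied covariance off-diagonal
        is the soft-thresholded correlation sign(r)(|r|-lam)."""
        r, lam = 0.6, 0.2
        R = np.array([[1.0, r], [r, 1.0]])
        Theta = glasso_fit(R, lam)
        Sigma = np.linalg.inv(Theta)
        assert Sigma[0, 1] == pytest.approx(np.sign(r) * (abs(r) - lam), abs=1e-6)

    @pytest.mark.parametrize("lam", [0.05, 0.2])
    def test_matches_direct_optimization_p2(self, lam):
        R = np.array([[1.0, 0.6], [0.6, 1.0]])
        Theta = glasso_fit(R, lam)
        oracle, f_oracle = direct_glasso_oracle(R, lam, x0=np.linalg.cholesky(Theta)[np.tril_indices(2)])
        assert np.max(np.abs(Theta - oracle)) < 1e-5

    def test_matches_sklearn_solver(self):
        """Cross-check against an independent coordinate-descent solver on a
        well-conditioned problem (where that solver itself converges)."""
        from sklearn.covariance import graphical_lasso as sk
        rng = np.random.default_rng(0)
        A = rng.standard_normal((500, 5))
        R = np.corrcoef(A.T)
        for lam in (0.02, 0.1):
            _, Ts = sk(R, alpha=lam, tol=1e-10, max_iter=2000)
            assert np.max(np.abs(glasso_fit(R, lam) - Ts)) < 1e-4

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(2), -0.1)


class TestEbicPath:
    def test_identity_correlation_selects_empty_network(self):
        net = sn.ebic_path(np.eye(5), n=200)
        assert net.n_edges == 0
        assert net.global_strength == 0.0

    def test_chain_support_recovered(self, chain_model):
        ds = sn.sample_ordinal_wave(chain_model, 5000, seed=20)
        net = sn.estimate_network(ds)
        W = net.W
        assert abs(W[0, 1]) > EDGE_EPS and abs(W[1, 2]) > EDGE_EPS
        assert abs(W[0, 2]) <= EDGE_EPS

    def test_edge_count_monotone_along_path(self, chain_model):
        """Edge count shrinks as the penalty grows.  (Exact lasso paths can
        in principle drop and re-add an edge; on a well-separated structure
        the count is monotone, which is what the path selection relies on.)"""
        ds = sn.sample_ordinal_wave(chain_model, 2000, seed=31)
        R = sn.correlation_matrix(ds)
        cfg = sn.GGMConfig(n_lambdas=25)
        counts = []
        Theta = None
        for lam in lambda_path(R.R, cfg):
            Theta = glasso_fit(R.R, lam, cfg, Theta_init=Theta)
            iu = np.triu_indices(R.R.shape[0], k=1)
            counts.append(int(np.sum(np.abs(Theta[iu]) > EDGE_EPS)))
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == 0 and counts[-1] >= 2

    def test_theta_pd_along_path(self, small_wave):
        _, ds = small_wave
        R = sn.correlation_matrix(ds)
        cfg = sn.GGMConfig(n_lambdas=15)
        Theta = None
        for lam in lambda_path(R.R, cfg):
            Theta = glasso_fit(R.R, lam, cfg, Theta_init=Theta)
            assert np.linalg.eigvalsh(Theta).min() > 0

    def test_node_permutation_permutes_network(self, small_wave):
        _, ds = small_wave
        R = sn.correlation_matrix(ds).R
        perm = np.array([2, 0, 4, 1, 5, 3])
        net = sn.ebic_path(R, n=400)
        net_p = sn.ebic_path(R[np.ix_(perm, perm)], n=400)
        assert np.allclose(net_p.W, net.W[np.ix_(perm, perm)], atol=1e-5)

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="effective n"):
            sn.ebic_path(np.eye(6), n=4)


class TestPrecisionToPcor:
    def test_diagonal_precision_gives_empty_network(self):
        assert np.allclose(sn.precision_to_pcor(np.diag([2.0, 3.0, 1.0])), 0.0)

    def test_two_node_identity_with_marginal_correlation(self):
        r = 0.45
        Theta = np.linalg.inv(np.array([[1.0, r], [r, 1.0]]))
        W = sn.precision_to_pcor(Theta)
        assert W[0, 1] == pytest.approx(r, abs=1e-12)

    def test_matches_ols_residual_correlations(self):
        """Partial correlation ij equals the correlation of residuals from
        regressing i and j on the remaining variables."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((5000, 3)) @ np.linalg.cholesky(
            np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])).T
        Theta = np.linalg.inv(np.cov(X.T))
        W = sn.precision_to_pcor(Theta)
        for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
            beta_i = np.polyfit(X[:, k], X[:, i], 1)
            beta_j = np.polyfit(X[:, k], X[:, j], 1)
            ri = X[:, i] - np.polyval(beta_i, X[:, k])
            rj = X[:, j] - np.polyval(beta_j, X[:, k])
            assert W[i, j] == pytest.approx(np.corrcoef(ri, rj)[0, 1], abs=1e-6)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            sn.precision_to_pcor(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestGlobalStrength:
    def test_arithmetic_and_symmetry_identity(self, small_wave):
        _, ds = small_wave
        net = sn.estimate_network(ds, sn.GGMConfig(n_lambdas=20))
        gs = sn.global_strength(net)
        assert gs == pytest.approx(0.5 * np.sum(np.abs(net.W)))
        assert gs == pytest.approx(0.5 * np.sum(sn.node_strength(net)))

    def test_two_edges(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[1, 2] = W[2, 1] = -0.2
        net = sn.GGMNetwork(W=W, Theta=np.eye(3), lambda_selected=0.1, ebic=0.0)
        assert sn.global_strength(net) == pytest.approx(0.5)


class TestEffectiveSampleSize:
    def test_rows_and_mean_pairwise_modes(self):
        vals = np.array([[0, 1, 2], [np.nan, np.nan, np.nan], [1, np.nan, 0]], float)
        ds = sn.OrdinalDataset(values=vals, item_codes=list("abc"))
        from sympnet.ggm import effective_sample_size
        assert effective_sample_size(ds, "rows") == 2
        # observed pairs: ab=1, ac=2, bc=1
        assert effective_sample_size(ds, "mean_pairwise") == pytest.approx(4 / 3)
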