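"""Sparse Gaussian graphical model estimation with EBIC penalty selection.

The network of conditional dependencies among items is estimated by the
graphical lasso: L1-penalised maximum likelihood for the precision matrix
Theta given the (latent) correlation matrix R, with the penalty applied to
off-diagonal entries only.  A log-spaced penalty path is scored by the
Extended Bayesian Information Criterion,

    EBIC(Theta) = -2 L + E log n + 4 E gamma log p,
    L = (n/2) (log det Theta - tr(R Theta)),

where E counts nonzero off-diagonal pairs, and the minimiser is returned as
a partial-correlation weight matrix W with

    W[i, j] = -Theta[i, j] / sqrt(Theta[i, i] Theta[j, j]).

Global strength — the network's overall connectivity — is the sum of
absolute edge weights over unordered pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import CorrelationMatrix, OrdinalDataset, correlation_matrix

__all__ = [
    "GGMConfig",
    "GGMNetwork",
    "glasso_fit",
    "ebic",
    "ebic_path",
    "precision_to_pcor",
    "global_strength",
    "estimate_network",
]

EDGE_EPS = 1e-8  # below this magnitude a weight counts as absent


class GlassoError(RuntimeError):
    """Raised when the penalised fit fails to converge."""


@dataclass(frozen=True)
class GGMConfig:
    """Tuning parameters of the regularised estimation.

    gamma : EBIC sparsity hyperparameter; 0.5 is the conservative standard
        for psychometric networks (0 recovers plain BIC).
    n_lambdas, lambda_min_ratio : the penalty path runs from the smallest
        lambda that empties the model down to lambda_max * lambda_min_ratio,
        log-spaced.
    convergence_tol, max_iter : inner-solver stopping rule.
    """

    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    convergence_tol: float = 1e-7
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


@dataclass
class GGMNetwork:
    """Selected sparse partial-correlation network."""

    W: np.ndarray
    Theta: np.ndarray
    lambda_selected: float
    ebic: float
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_labels:
            self.node_labels = [f"node{i + 1}" for i in range(self.W.shape[0])]

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.sum(np.abs(self.W[iu]) > EDGE_EPS))

    @property
    def global_strength(self) -> float:
        return global_strength(self)

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.p, k=1)
        keep = np.abs(self.W[iu]) > EDGE_EPS
        return pd.DataFrame({
            "node_i": np.asarray(self.node_labels)[iu[0][keep]],
            "node_j": np.asarray(self.node_labels)[iu[1][keep]],
            "weight": self.W[iu][keep],
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.node_labels, columns=self.node_labels)


def _soft_threshold_offdiag(A: np.ndarray, t: float) -> np.ndarray:
    out = np.sign(A) * np.maximum(np.abs(A) - t, 0.0)
    np.fill_diagonal(out, np.diag(A))
    return out


def glasso_fit(R: np.ndarray | CorrelationMatrix, lam: float,
               config: GGMConfig = GGMConfig(),
               Theta_init: np.ndarray | None = None) -> np.ndarray:
    """Graphical-lasso precision estimate at a single penalty.

    Minimises tr(R Theta) - log det Theta + lam * sum_{i!=j} |Theta_ij|
    (the penalty touches off-diagonals only) by proximal gradient descent
    with backtracking over the positive-definite cone: gradient step on the
    smooth part (gradient R - inv(Theta)), soft-thresholding of the
    off-diagonals, step size reset to eigmin(Theta)^2 each iteration, which
    keeps iterates positive definite with at most a few halvings.
    Convergence when the largest parameter change drops below
    ``config.convergence_tol``.  ``Theta_init`` enables warm starts along a
    penalty path.  lam = 0 is the unpenalised limit, computed by direct
    inversion.
    """
    Rm = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    if lam == 0.0:
        return np.linalg.inv(Rm)

    Theta = (Theta_init.copy() if Theta_init is not None
             else np.diag(1.0 / np.diag(Rm)))
    t = float(np.linalg.eigvalsh(Theta).min()) ** 2
    prev_Theta = prev_grad = None
    for it in range(config.max_iter):
        cho = np.linalg.cholesky(Theta)
        grad = Rm - np.linalg.inv(Theta)
        g0 = float(np.sum(Rm * Theta)) - 2.0 * float(np.sum(np.log(np.diag(cho))))
        # Barzilai-Borwein step from the previous iterate, safeguarded below
        if prev_Theta is not None:
            dT = Theta - prev_Theta
            dG = grad - prev_grad
            denom = float(np.sum(dT * dG))
            if denom > 0:
                t = float(np.sum(dT * dT)) / denom
        prev_Theta, prev_grad = Theta, grad
        while True:
            Tn = _soft_threshold_offdiag(Theta - t * grad, t * lam)
            try:
                chon = np.linalg.cholesky(Tn)
            except np.linalg.LinAlgError:
                t *= 0.5
                continue
            gn = float(np.sum(Rm * Tn)) - 2.0 * float(np.sum(np.log(np.diag(chon))))
            D = Tn - Theta
            if gn <= g0 + float(np.sum(grad * D)) + float(np.sum(D * D)) / (2.0 * t) + 1e-12:
                break
            t *= 0.5
        delta = float(np.max(np.abs(Tn - Theta)))
        Theta = Tn
        if delta < config.convergence_tol:
            return Theta
    raise GlassoError(
        f"glasso did not converge at lambda={lam:.4g} after {config.max_iter} iterations")


def precision_to_pcor(Theta: np.ndarray) -> np.ndarray:
    """Partial-correlation weights implied by a precision matrix."""
    Theta = np.asarray(Theta, dtype=float)
    d = np.diag(Theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal")
    W = -Theta / np.sqrt(np.outer(d, d))
    np.fill_diagonal(W, 0.0)
    return 0.5 * (W + W.T)


def ebic(Theta: np.ndarray, R: np.ndarray, n: float, gamma: float) -> float:
    """Extended BIC of a fitted precision matrix against correlation R."""
    p = Theta.shape[0]
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return np.inf
    L = 0.5 * n * (logdet - np.trace(R @ Theta))
    iu = np.triu_indices(p, k=1)
    E = int(np.sum(np.abs(Theta[iu]) > EDGE_EPS))
    return float(-2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def lambda_path(R: np.ndarray, config: GGMConfig) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (empty model) downward."""
    iu = np.triu_indices(R.shape[0], k=1)
    lam_max = float(np.max(np.abs(R[iu])))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambdas)


def ebic_path(
    R: CorrelationMatrix | np.ndarray,
    n: float,
    config: GGMConfig = GGMConfig(),
    node_labels: list[str] | None = None,
) -> GGMNetwork:
    """Fit the penalty path and return the EBIC-minimising network.

    Ties on EBIC break toward the larger penalty (sparser model).  A
    warning is issued when n < p, where regularised estimates are the only
    thing keeping the problem identified.
    """
    if isinstance(R, CorrelationMatrix):
        labels = node_labels or list(R.item_codes)
        Rm = R.R
    else:
        Rm = np.asarray(R, dtype=float)
        labels = node_labels or [f"node{i + 1}" for i in range(Rm.shape[0])]
    p = Rm.shape[0]
    if n < p:
        warnings.warn(f"effective n ({n}) below node count ({p}); "
                      "estimates rely heavily on regularization")

    lams = lambda_path(Rm, config)  # descending: sparsest first
    best = None
    Theta = None
    for lam in lams:
        Theta = glasso_fit(Rm, lam, config, Theta_init=Theta)
        score = ebic(Theta, Rm, n, config.gamma)
        # strict < keeps the earlier (larger-lambda, sparser) fit on ties
        if best is None or score < best[0]:
            best = (score, lam, Theta)
    score, lam, Theta = best
    return GGMNetwork(W=precision_to_pcor(Theta), Theta=Theta,
                      lambda_selected=float(lam), ebic=score,
                      node_labels=labels)


def global_strength(network: GGMNetwork) -> float:
    """Sum of absolute edge weights over unordered node pairs."""
    iu = np.triu_indices(network.p, k=1)
    return float(np.sum(np.abs(network.W[iu])))


def effective_sample_size(data: OrdinalDataset, mode: str = "rows") -> float:
    """Scalar n for the EBIC under pairwise-complete estimation.

    ``"rows"`` (default): rows with at least one observed item at the wave;
    ``"mean_pairwise"``: mean of the per-pair observation counts.
    """
    mask = data.observed_mask()
    if mode == "rows":
        return float(np.sum(mask.any(axis=1)))
    if mode == "mean_pairwise":
        m = mask.astype(float)
        counts = m.T @ m
        iu = np.triu_indices(data.n_items, k=1)
        return float(np.mean(counts[iu]))
    raise ValueError(f"unknown effective-n mode {mode!r}")


def estimate_network(
    data: OrdinalDataset,
    config: GGMConfig = GGMConfig(),
    pairwise_complete: bool = True,
    effective_n_mode: str = "rows",
) -> GGMNetwork:
    """Full estimation step: latent correlations then EBIC-glasso selection."""
    R = correlation_matrix(data, pairwise_complete=pairwise_complete)
    n_eff = effective_sample_size(data, effective_n_mode)
    return ebic_path(R, n_eff, config)
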