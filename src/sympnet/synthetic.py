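"""Synthetic longitudinal ordinal data with a known ground-truth network.

Generates the kind of data the estimation pipeline consumes — ordinal item
responses thresholded from a latent multivariate normal whose precision
matrix encodes a sparse partial-correlation network — so that every
downstream stage (polychoric estimation, EBIC-glasso, centrality,
bootstraps, permutation comparison) can be validated by parameter recovery.

The default design emulates a 4-wave longitudinal symptom study: ~300
subjects, 4-level ordinal items, within-subject dependence across waves,
and missing-completely-at-random wave dropout that yields a complete-case
subset of roughly 56% of subjects (missing rate 0.135 per wave,
0.865**4 ~ 0.56).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .correlations import OrdinalDataset

__all__ = [
    "TrueNetworkModel",
    "LongitudinalDesign",
    "make_true_network",
    "sample_ordinal_wave",
    "sample_longitudinal",
    "save_ground_truth",
]

#: default per-wave dropout probability; 1 - (1-0.135)**4 leaves ~56% complete
DEFAULT_MISSING_RATE = 0.135
#: minimum eigenvalue enforced on the precision matrix during construction
MIN_PRECISION_EIG = 0.05
#: default latent cut points for 4-level items (standard-normal units)
DEFAULT_THRESHOLDS = (-1.0, 0.0, 1.0)


class ConstructionError(RuntimeError):
    """Raised when a positive-definite precision matrix cannot be built."""


@dataclass
class TrueNetworkModel:
    """Ground-truth Gaussian graphical model behind the ordinal items.

    ``Omega`` is the precision matrix of the latent variables;
    ``Pcor_true[i, j] = -Omega[i, j] / sqrt(Omega[i, i] * Omega[j, j])``
    is the implied partial-correlation network (unit diagonal by
    convention).  ``thresholds`` are the per-item ordered cut points on the
    latent standard-normal scale; items have ``n_levels`` categories.
    """

    p: int
    Omega: np.ndarray
    Pcor_true: np.ndarray
    thresholds: np.ndarray  # (p, n_levels - 1)
    n_levels: int

    def __post_init__(self) -> None:
        if np.linalg.eigvalsh(self.Omega).min() <= 0:
            raise ConstructionError("precision matrix is not positive definite")
        if self.thresholds.shape != (self.p, self.n_levels - 1):
            raise ValueError("thresholds must be (p, n_levels-1)")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")

    def latent_correlation(self) -> np.ndarray:
        """Marginal correlation matrix of the latent normal (unit variances)."""
        Sigma = np.linalg.inv(self.Omega)
        d = np.sqrt(np.diag(Sigma))
        return Sigma / np.outer(d, d)


@dataclass
class LongitudinalDesign:
    """Shape of the longitudinal study the generator emulates."""

    n_subjects: int = 306
    n_timepoints: int = 4
    subject_corr: float = 0.5
    missing_rate: float = DEFAULT_MISSING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if not 0.0 <= self.subject_corr < 1.0:
            raise ValueError("subject_corr must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def make_true_network(
    p: int,
    edge_prob: float,
    weight_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    n_levels: int = 4,
    thresholds: np.ndarray | None = None,
    neg_prob: float = 0.0,
    max_loading_iter: int = 100,
) -> TrueNetworkModel:
    """Draw a sparse ground-truth partial-correlation network.

    Edges are sampled i.i.d. Bernoulli(``edge_prob``) over unordered pairs;
    edge weights uniform on ``weight_range`` (sign flipped with probability
    ``neg_prob``).  The precision matrix starts as I minus the weighted
    adjacency and is diagonally loaded until its minimum eigenvalue reaches
    0.05, then rescaled to unit partial variances, which preserves both the
    edge support and the partial-correlation signs (shrinking magnitudes
    only when loading was needed).
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    lo, hi = weight_range
    if not (-1 < lo <= hi < 1):
        raise ValueError("weight_range must lie within (-1, 1)")

    rng = np.random.default_rng(seed)
    W = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    edges = rng.random(len(iu[0])) < edge_prob
    w = rng.uniform(lo, hi, size=len(iu[0]))
    sign = np.where(rng.random(len(iu[0])) < neg_prob, -1.0, 1.0)
    W[iu] = np.where(edges, w * sign, 0.0)
    W = W + W.T

    Omega = np.eye(p) - W
    delta = 0.0
    for _ in range(max_loading_iter):
        if np.linalg.eigvalsh(Omega + delta * np.eye(p)).min() >= MIN_PRECISION_EIG:
            break
        delta = 0.05 if delta == 0.0 else delta * 1.5
    else:
        raise ConstructionError("diagonal loading failed to reach positive definiteness")
    Omega = Omega + delta * np.eye(p)
    d = np.sqrt(np.diag(Omega))
    Omega = Omega / np.outer(d, d)

    Pcor = -Omega / np.sqrt(np.outer(np.diag(Omega), np.diag(Omega)))
    np.fill_diagonal(Pcor, 1.0)

    if thresholds is None:
        base = np.asarray(DEFAULT_THRESHOLDS, dtype=float)
        if n_levels != len(base) + 1:
            # evenly spaced cut points covering +-1.5 latent SDs
            base = np.linspace(-1.5, 1.5, n_levels - 1)
        thresholds = np.tile(base, (p, 1))
    thresholds = np.asarray(thresholds, dtype=float)

    return TrueNetworkModel(p=p, Omega=Omega, Pcor_true=Pcor,
                            thresholds=thresholds, n_levels=n_levels)


def _discretize(latent: np.ndarray, model: TrueNetworkModel) -> np.ndarray:
    out = np.empty_like(latent)
    for j in range(model.p):
        out[:, j] = np.searchsorted(model.thresholds[j], latent[:, j], side="right")
    return out


def sample_ordinal_wave(
    model: TrueNetworkModel,
    n: int,
    seed: int = 0,
    time_label: str = "T1",
) -> OrdinalDataset:
    """Sample one cross-sectional wave of ordinal responses.

    Latent vectors are multivariate normal with covariance inv(Omega)
    rescaled to unit variances; each coordinate is cut at the item's
    thresholds, giving levels 0 .. n_levels-1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.latent_correlation())
    latent = rng.standard_normal((n, model.p)) @ L.T
    values = _discretize(latent, model)
    codes = [f"item{j + 1}" for j in range(model.p)]
    return OrdinalDataset(values=values, item_codes=codes,
                          item_kind=["ordinal"] * model.p, time_label=time_label)


def sample_longitudinal(
    models: list[TrueNetworkModel],
    design: LongitudinalDesign,
) -> list[OrdinalDataset]:
    """Sample aligned multi-wave data with within-subject dependence.

    Each subject carries a latent trait vector ``u ~ N(0, I_p)``; the wave-t
    latent response is ``L_t (sqrt(c) u + sqrt(1-c) e_t)`` with ``e_t``
    i.i.d. standard normal and ``L_t`` the Cholesky factor of wave t's
    latent correlation, so every wave keeps its own marginal network while
    any item correlates across waves at roughly ``c = subject_corr``.
    Missingness is MCAR: a subject's whole wave is dropped with probability
    ``missing_rate``, independently per (subject, wave).
    """
    if len(models) != design.n_timepoints:
        raise ValueError("need one TrueNetworkModel per time point")
    p = models[0].p
    n_levels = models[0].n_levels
    for m in models[1:]:
        if m.p != p or m.n_levels != n_levels:
            raise ValueError("all wave models must share p and n_levels")

    rng = np.random.default_rng(design.seed)
    n, T, c = design.n_subjects, design.n_timepoints, design.subject_corr
    u = rng.standard_normal((n, p))
    codes = [f"item{j + 1}" for j in range(p)]
    waves: list[OrdinalDataset] = []
    for t, model in enumerate(models):
        e = rng.standard_normal((n, p))
        L = np.linalg.cholesky(model.latent_correlation())
        latent = (np.sqrt(c) * u + np.sqrt(1.0 - c) * e) @ L.T
        values = _discretize(latent, model)
        missing = rng.random(n) < design.missing_rate
        values[missing, :] = np.nan
        waves.append(OrdinalDataset(values=values, item_codes=codes,
                                    item_kind=["ordinal"] * p,
                                    time_label=f"T{t + 1}",
                                    subject_ids=np.arange(n)))
    return waves


def save_ground_truth(model: TrueNetworkModel, path: str | Path,
                      seed: int | None = None) -> None:
    """Write the generator's ground truth (precision, thresholds) as JSON."""
    payload = {
        "p": model.p,
        "n_levels": model.n_levels,
        "precision": model.Omega.tolist(),
        "partial_correlations": model.Pcor_true.tolist(),
        "thresholds": model.thresholds.tolist(),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
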