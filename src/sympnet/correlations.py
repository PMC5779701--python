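"""Latent-correlation estimation for mixed ordinal/continuous data.

Network estimation for ordinal symptom items starts from a correlation
matrix of the *latent* continuous variables assumed to underlie the observed
categories.  This module provides the standard two-step estimators:

* polychoric (ordinal-ordinal; tetrachoric as the binary special case),
* polyserial (continuous-ordinal),
* product-moment (continuous-continuous),

dispatched per pair by :func:`correlation_matrix`, with pairwise-complete
observation handling and eigenvalue-clipping repair of indefinite matrices.

The two-step scheme first fixes each item's thresholds from its marginal
category proportions (inverse normal CDF of cumulative proportions) and then
maximises the bivariate likelihood over the single correlation parameter.
Bivariate-normal rectangle probabilities use Owen's T function, accurate to
well below the 1e-8 tolerance used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "OrdinalDataset",
    "CorrelationMatrix",
    "bvn_cdf",
    "estimate_thresholds",
    "polychoric_pair",
    "polyserial_pair",
    "correlation_matrix",
    "nearest_pd_repair",
]

RHO_BOUND = 0.999
DEFAULT_MIN_PAIRWISE_N = 10
PD_EIG_FLOOR = 1e-6


class EstimationError(ValueError):
    """Raised when a correlation cannot be estimated from the data given."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class OrdinalDataset:
    """Subjects x items data with missingness, as floats with NaN markers.

    Parameters
    ----------
    values : (n_subjects, n_items) float array; NaN = missing.  Ordinal and
        binary items hold non-negative integer levels.
    item_codes : item labels (e.g. ``cesd1`` ... ``cesd20``, ``gse``, ``rx``).
    item_kind : per item, one of ``"ordinal"``, ``"continuous"``, ``"binary"``.
    time_label : wave identifier (e.g. ``"T1"``).
    subject_ids : optional per-row subject identifiers.
    """

    values: np.ndarray
    item_codes: list[str]
    item_kind: list[str] = field(default_factory=list)
    time_label: str = ""
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x items)")
        if len(self.item_codes) != self.values.shape[1]:
            raise ValueError("item_codes length must match number of columns")
        if not self.item_kind:
            self.item_kind = ["ordinal"] * self.values.shape[1]
        if len(self.item_kind) != self.values.shape[1]:
            raise ValueError("item_kind length must match number of columns")
        for k in self.item_kind:
            if k not in ("ordinal", "continuous", "binary"):
                raise ValueError(f"unknown item kind {k!r}")
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.values.shape[0])
        else:
            self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_codes)
        df.insert(0, "time", self.time_label)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class CorrelationMatrix:
    """Estimated latent correlation matrix with estimation metadata."""

    R: np.ndarray
    item_codes: list[str]
    thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    n_pairwise: np.ndarray | None = None
    pd_repaired: bool = False

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.item_codes, columns=self.item_codes)


# ---------------------------------------------------------------------------
# Bivariate-normal CDF (Owen's T)
# ---------------------------------------------------------------------------

def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate-normal CDF P(X <= h, Y <= k) with correlation rho.

    Vectorised over ``h``/``k`` (broadcast together); ``rho`` is scalar.
    Uses Owen's T representation; magnitudes below 1e-10 are clamped
    (sign-preserving) so the branch terms keep well-defined ratios — the
    CDF is continuous there and the clamp error (~4e-11) is far below
    estimation tolerances.  Infinite arguments reduce to the
    univariate/zero limits.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -1.0, 1.0))

    if rho == 1.0:
        return special.ndtr(np.minimum(h, k))
    if rho == -1.0:
        return np.maximum(special.ndtr(h) + special.ndtr(k) - 1.0, 0.0)

    hh = np.where(np.abs(h) < 1e-10, np.where(h < 0, -1e-10, 1e-10), h)
    kk = np.where(np.abs(k) < 1e-10, np.where(k < 0, -1e-10, 1e-10), k)
    s = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (kk - rho * hh) / (hh * s)
        ak = (hh - rho * kk) / (kk * s)
        # infinite h or k: univariate limits handled after the main formula
        finite = np.isfinite(hh) & np.isfinite(kk)
        ah = np.where(finite, ah, 0.0)
        ak = np.where(finite, ak, 0.0)
        hk = hh * kk
        beta = np.where((hk > 0) | ((hk == 0) & (hh + kk >= 0)), 0.0, 0.5)
        out = (
            0.5 * (special.ndtr(hh) + special.ndtr(kk))
            - special.owens_t(hh, ah)
            - special.owens_t(kk, ak)
            - beta
        )
    # limits for infinite arguments
    out = np.where(h == np.inf, special.ndtr(k), out)
    out = np.where(k == np.inf, np.where(h == np.inf, 1.0, special.ndtr(h)), out)
    out = np.where((h == -np.inf) | (k == -np.inf), 0.0, out)
    return np.clip(out, 0.0, 1.0)


def _rectangle_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of the discretised bivariate normal.

    ``tau_x``/``tau_y`` are threshold vectors *including* the -inf/+inf
    boundaries; the result has shape (len(tau_x)-1, len(tau_y)-1).
    """
    H, K = np.meshgrid(tau_x, tau_y, indexing="ij")
    F = bvn_cdf(H, K, rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 0.0, 1.0)


def _table_nll_factory(tab, tau_x, tau_y):
    """Negative log-likelihood of a contingency table as a function of rho.

    Grid geometry (threshold meshes, infinity masks) is precomputed once so
    the optimizer's inner evaluations stay cheap.
    """
    H, K = np.meshgrid(tau_x, tau_y, indexing="ij")
    h, k = H.ravel(), K.ravel()
    hh = np.where(np.abs(h) < 1e-10, np.where(h < 0, -1e-10, 1e-10), h)
    kk = np.where(np.abs(k) < 1e-10, np.where(k < 0, -1e-10, 1e-10), k)
    finite = np.isfinite(hh) & np.isfinite(kk)
    hk = hh * kk
    with np.errstate(invalid="ignore"):
        beta = np.where((hk > 0) | ((hk == 0) & (hh + kk >= 0)), 0.0, 0.5)
    base = 0.5 * (special.ndtr(hh) + special.ndtr(kk)) - beta
    uni_h = h == np.inf
    uni_k = k == np.inf
    both = uni_h & uni_k
    zero = (h == -np.inf) | (k == -np.inf)
    ndtr_k, ndtr_h = special.ndtr(k), special.ndtr(h)
    shape = H.shape

    def nll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        with np.errstate(divide="ignore", invalid="ignore"):
            ah = np.where(finite, (kk - rho * hh) / (hh * s), 0.0)
            ak = np.where(finite, (hh - rho * kk) / (kk * s), 0.0)
        F = base - special.owens_t(hh, ah) - special.owens_t(kk, ak)
        F = np.where(uni_h, ndtr_k, F)
        F = np.where(uni_k, ndtr_h, F)
        F = np.where(both, 1.0, F)
        F = np.where(zero, 0.0, F).reshape(shape)
        P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
        return -float(np.sum(tab * np.log(np.maximum(P, 1e-300))))

    return nll


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def estimate_thresholds(column: np.ndarray, name: str = "item") -> np.ndarray:
    """First-stage threshold estimates for one ordinal item.

    Threshold k is the standard-normal quantile of the cumulative observed
    proportion at or below category k.  Empty boundary categories contribute
    no threshold (they are merged away).  Raises on a constant column.
    """
    col = np.asarray(column, dtype=float)
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise EstimationError(f"no observed values for item {name!r}")
    levels, counts = np.unique(col, return_counts=True)
    if levels.size < 2:
        raise EstimationError(f"item {name!r} is constant; thresholds undefined")
    cum = np.cumsum(counts)[:-1] / col.size
    return stats.norm.ppf(cum)


def _observed_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Contingency table of two ordinal columns over their observed levels."""
    xl = np.unique(x)
    yl = np.unique(y)
    xi = np.searchsorted(xl, x)
    yi = np.searchsorted(yl, y)
    tab = np.zeros((xl.size, yl.size))
    np.add.at(tab, (xi, yi), 1.0)
    return tab


# ---------------------------------------------------------------------------
# Polychoric
# ---------------------------------------------------------------------------

def polychoric_pair(
    x: np.ndarray,
    y: np.ndarray,
    min_pairwise_n: int = DEFAULT_MIN_PAIRWISE_N,
    xatol: float = 1e-6,
) -> float:
    """Two-step polychoric correlation of two ordinal columns.

    Thresholds are fixed from the pairwise-complete margins; the correlation
    maximises the contingency-table likelihood with bivariate-normal cell
    probabilities, constrained to [-0.999, 0.999].  Binary items reduce to
    the tetrachoric special case of the same likelihood.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < min_pairwise_n:
        raise EstimationError(
            f"only {x.size} pairwise-complete cases (minimum {min_pairwise_n})"
        )
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise EstimationError("item constant on the pairwise-complete subset")

    tab = _observed_table(x, y)
    tau_x = np.concatenate(([-np.inf], estimate_thresholds(x), [np.inf]))
    tau_y = np.concatenate(([-np.inf], estimate_thresholds(y), [np.inf]))

    res = optimize.minimize_scalar(
        _table_nll_factory(tab, tau_x, tau_y),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": xatol},
    )
    rho = float(res.x)
    # flat-likelihood / perfect-association tables end up at the boundary;
    # snap within optimizer resolution so callers can detect it
    if RHO_BOUND - abs(rho) < 10 * xatol:
        rho = float(np.sign(rho) * RHO_BOUND)
    return rho


# ---------------------------------------------------------------------------
# Polyserial
# ---------------------------------------------------------------------------

def _polyserial_nll(rho: float, z: np.ndarray, lo: np.ndarray,
                    hi: np.ndarray) -> float:
    s = np.sqrt(1.0 - rho * rho)
    with np.errstate(invalid="ignore"):
        upper = special.ndtr((hi - rho * z) / s)
        lower = special.ndtr((lo - rho * z) / s)
    return -float(np.sum(np.log(np.maximum(upper - lower, 1e-300))))


def polyserial_pair(
    x: np.ndarray,
    y: np.ndarray,
    min_pairwise_n: int = DEFAULT_MIN_PAIRWISE_N,
    xatol: float = 1e-6,
) -> float:
    """Polyserial correlation: continuous ``x`` against ordinal ``y``.

    Conditional-likelihood ML under the latent bivariate-normal model with
    the continuous margin standardised empirically and the ordinal
    thresholds fixed from the margins (two-step), bounded to [-0.999, 0.999].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < min_pairwise_n:
        raise EstimationError(
            f"only {x.size} pairwise-complete cases (minimum {min_pairwise_n})"
        )
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise EstimationError("continuous variable has zero variance")
    if np.unique(y).size < 2:
        raise EstimationError("ordinal item constant on the pairwise subset")

    z = (x - np.mean(x)) / sd
    tau = np.concatenate(([-np.inf], estimate_thresholds(y), [np.inf]))
    levels = np.unique(y)
    idx = np.searchsorted(levels, y)
    lo, hi = tau[idx], tau[idx + 1]

    res = optimize.minimize_scalar(
        _polyserial_nll,
        bounds=(-RHO_BOUND, RHO_BOUND),
        args=(z, lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Positive-definite repair
# ---------------------------------------------------------------------------

def nearest_pd_repair(R: np.ndarray, eig_floor: float = PD_EIG_FLOOR) -> np.ndarray:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Eigenvalues below ``eig_floor`` are raised to it and the matrix is
    rescaled back to unit diagonal.  Idempotent (up to floating error) on
    matrices that are already positive definite.
    """
    R = np.asarray(R, dtype=float)
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() >= eig_floor:
        return R
    w = np.maximum(w, eig_floor)
    out = (V * w) @ V.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


# ---------------------------------------------------------------------------
# Full matrix with per-pair dispatch
# ---------------------------------------------------------------------------

def correlation_matrix(
    data: OrdinalDataset,
    pairwise_complete: bool = True,
    min_pairwise_n: int = DEFAULT_MIN_PAIRWISE_N,
) -> CorrelationMatrix:
    """Latent correlation matrix of a mixed ordinal/continuous dataset.

    Per-pair method by item kinds: ordinal/binary vs ordinal/binary ->
    polychoric (tetrachoric for 2x2); continuous vs ordinal -> polyserial;
    continuous vs continuous -> product-moment.  ``pairwise_complete``
    selects pairwise deletion (each pair uses all cases observed on both
    items); otherwise listwise deletion is applied first.  Indefinite
    results are repaired by eigenvalue clipping, recorded in
    ``pd_repaired``.
    """
    p = data.n_items
    if p < 3:
        raise ValueError("correlation_matrix requires at least 3 items")
    values = data.values
    if not pairwise_complete:
        keep = data.observed_mask().all(axis=1)
        values = values[keep]

    R = np.eye(p)
    n_pair = np.zeros((p, p), dtype=int)
    np.fill_diagonal(n_pair, (~np.isnan(values)).sum(axis=0))
    thresholds: dict[str, np.ndarray] = {}
    for j, code in enumerate(data.item_codes):
        if data.item_kind[j] in ("ordinal", "binary"):
            col = values[:, j]
            thresholds[code] = estimate_thresholds(col[~np.isnan(col)], code)

    bad_pairs: list[tuple[str, str, int]] = []
    for i in range(p):
        for j in range(i + 1, p):
            xi, xj = values[:, i], values[:, j]
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            n_pair[i, j] = n_pair[j, i] = int(ok.sum())
            if ok.sum() < min_pairwise_n:
                bad_pairs.append((data.item_codes[i], data.item_codes[j], int(ok.sum())))
                continue
            ki, kj = data.item_kind[i], data.item_kind[j]
            disc_i = ki in ("ordinal", "binary")
            disc_j = kj in ("ordinal", "binary")
            if disc_i and disc_j:
                r = polychoric_pair(xi, xj, min_pairwise_n)
            elif disc_i != disc_j:
                cont, disc = (xi, xj) if not disc_i else (xj, xi)
                r = polyserial_pair(cont, disc, min_pairwise_n)
            else:
                r = float(np.corrcoef(xi[ok], xj[ok])[0, 1])
            R[i, j] = R[j, i] = r

    if bad_pairs:
        desc = ", ".join(f"{a}-{b} (n={n})" for a, b, n in bad_pairs)
        raise EstimationError(f"pairs below minimum pairwise n: {desc}")

    repaired = False
    if np.linalg.eigvalsh(R).min() < 0:
        R = nearest_pd_repair(R)
        repaired = True
        warnings.warn("correlation matrix was indefinite; repaired by eigenvalue clipping")

    return CorrelationMatrix(
        R=R,
        item_codes=list(data.item_codes),
        thresholds=thresholds,
        n_pairwise=n_pair,
        pd_repaired=repaired,
    )
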