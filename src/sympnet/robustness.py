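"""Bootstrap accuracy and stability of estimated networks.

Two resampling routines, following the standard accuracy workflow for
psychometric networks:

* nonparametric bootstrap — resample subjects with replacement, re-run the
  whole estimation (latent correlations + EBIC-glasso), and summarise each
  edge's replicate distribution as a 95% quantile interval;
* case-dropping subset bootstrap — re-estimate on progressively smaller
  random subsets and correlate subset centralities with the full-sample
  values; the correlation-stability (CS) coefficient is the largest drop
  proportion at which at least 95% of replicates still correlate >= 0.7
  with the full sample.  CS above 0.25 is conventionally read as moderate
  stability, above 0.5 as strong.

Bootstrapped difference tests for edges and centralities reuse the
nonparametric replicate store: a pair differs when the 95% interval of the
replicate-wise difference excludes zero (deliberately uncorrected for
multiplicity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import centrality_table, node_strength
from .correlations import EstimationError, OrdinalDataset
from .ggm import GGMConfig, GGMNetwork, GlassoError, estimate_network

__all__ = [
    "BootstrapSpec",
    "EdgeCITable",
    "StabilityResult",
    "nonparametric_boot",
    "case_dropping_boot",
    "cs_coefficient",
    "edge_difference_test",
    "centrality_difference_test",
]

MAX_FAILURE_FRACTION = 0.10


class BootstrapError(RuntimeError):
    """Raised when too many bootstrap replicates fail to estimate."""


@dataclass(frozen=True)
class BootstrapSpec:
    """Settings shared by the bootstrap routines."""

    n_boot: int = 1000
    drop_proportions: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))
    stability_cor_threshold: float = 0.7
    stability_prob: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if any(not 0 < q < 1 for q in self.drop_proportions):
            raise ValueError("drop proportions must lie in (0, 1)")


@dataclass
class EdgeCITable:
    """Per-edge point estimates with bootstrap 95% quantile intervals.

    ``replicates`` keeps the raw (n_boot, n_pairs) edge-weight draws so the
    difference tests can reuse them without re-estimating.
    """

    node_labels: list[str]
    pairs: list[tuple[int, int]]
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_replicates: int
    n_failed: int
    replicates: np.ndarray | None = None
    strength_replicates: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        labels = np.asarray(self.node_labels)
        return pd.DataFrame({
            "node_i": [labels[i] for i, _ in self.pairs],
            "node_j": [labels[j] for _, j in self.pairs],
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "n_replicates": self.n_replicates,
        })


@dataclass
class StabilityResult:
    """Case-dropping stability curves and the CS coefficient."""

    metric: str
    drop_proportions: np.ndarray
    correlations: dict[float, np.ndarray]  # drop proportion -> replicate corrs
    cs_coefficient: float
    cor_threshold: float
    prob_threshold: float

    def curve(self) -> pd.DataFrame:
        rows = []
        for q in self.drop_proportions:
            c = self.correlations[float(q)]
            rows.append({
                "drop_proportion": q,
                "mean_correlation": np.mean(c) if c.size else np.nan,
                "q05": np.quantile(c, 0.05) if c.size else np.nan,
                "prop_above_threshold": np.mean(c >= self.cor_threshold) if c.size else np.nan,
            })
        return pd.DataFrame(rows)


def _edge_vector(network: GGMNetwork) -> np.ndarray:
    iu = np.triu_indices(network.p, k=1)
    return network.W[iu]


def nonparametric_boot(
    data: OrdinalDataset,
    spec: BootstrapSpec,
    config: GGMConfig = GGMConfig(),
) -> EdgeCITable:
    """Subject-resampling bootstrap of the edge weights.

    Each replicate resamples subjects with replacement (replicate b seeded
    with spec.seed + b, so partial runs are resumable) and re-runs the full
    correlation + EBIC-glasso pipeline.  Replicates whose estimation fails
    are skipped and counted; more than 10% failures aborts.  The point
    estimate can fall outside the resampled quantiles under regularisation;
    that is flagged rather than forbidden.
    """
    full = estimate_network(data, config)
    p = full.p
    iu = np.triu_indices(p, k=1)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    est = _edge_vector(full)

    reps, strengths = [], []
    n_failed = 0
    n = data.n_subjects
    for b in range(spec.n_boot):
        rng = np.random.default_rng(spec.seed + b)
        idx = rng.integers(0, n, size=n)
        boot = OrdinalDataset(values=data.values[idx], item_codes=data.item_codes,
                              item_kind=list(data.item_kind),
                              time_label=data.time_label)
        try:
            net = estimate_network(boot, config)
        except (EstimationError, GlassoError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        reps.append(_edge_vector(net))
        strengths.append(node_strength(net))
    if n_failed > MAX_FAILURE_FRACTION * spec.n_boot:
        raise BootstrapError(f"{n_failed}/{spec.n_boot} bootstrap replicates failed")

    R = np.asarray(reps)
    S = np.asarray(strengths)
    flags = []
    if R.shape[0] < 2:
        lower = upper = R[0] if R.shape[0] else np.full_like(est, np.nan)
        flags.append("degenerate: fewer than 2 successful replicates")
    else:
        lower = np.quantile(R, 0.025, axis=0)
        upper = np.quantile(R, 0.975, axis=0)
    outside = (est < lower) | (est > upper)
    if np.any(outside):
        flags.append(f"{int(outside.sum())} point estimates outside their bootstrap interval")

    return EdgeCITable(node_labels=list(full.node_labels), pairs=pairs,
                       estimate=est, lower=lower, upper=upper,
                       n_replicates=R.shape[0], n_failed=n_failed,
                       replicates=R, strength_replicates=S, flags=flags)


def _centrality_values(network: GGMNetwork, metric: str) -> np.ndarray:
    if metric == "strength":
        return node_strength(network)
    table = centrality_table(network, standardized=False)
    return getattr(table, metric)


def cs_coefficient(correlations: dict[float, np.ndarray],
                   cor_threshold: float = 0.7,
                   prob_threshold: float = 0.95) -> float:
    """Largest drop proportion keeping >= prob_threshold of replicates
    correlated >= cor_threshold with the full sample; 0 if none qualifies."""
    qualifying = [q for q, c in correlations.items()
                  if c.size > 0 and np.mean(c >= cor_threshold) >= prob_threshold]
    return max(qualifying) if qualifying else 0.0


def case_dropping_boot(
    data: OrdinalDataset,
    spec: BootstrapSpec,
    metric: str = "strength",
    config: GGMConfig = GGMConfig(),
    corr_method: str = "pearson",
) -> StabilityResult:
    """Case-dropping subset bootstrap of a centrality metric.

    For each drop proportion, n_boot subsets are drawn without replacement,
    the network re-estimated, and the subset centralities correlated
    (product-moment by default, ``corr_method="spearman"`` optional) with
    the full-sample values across nodes.  Subsets smaller than p + 5
    subjects are skipped with a warning.
    """
    if metric not in ("strength", "betweenness", "closeness"):
        raise ValueError(f"unknown centrality metric {metric!r}")
    full = estimate_network(data, config)
    ref = _centrality_values(full, metric)
    n, p = data.n_subjects, data.n_items

    correlations: dict[float, np.ndarray] = {}
    for q in spec.drop_proportions:
        keep = int(round(n * (1.0 - q)))
        if keep < p + 5:
            warnings.warn(f"drop proportion {q} leaves {keep} < p+5 subjects; skipped")
            correlations[float(q)] = np.array([])
            continue
        vals = []
        n_failed = 0
        for b in range(spec.n_boot):
            rng = np.random.default_rng(spec.seed + b + int(round(q * 1000)) * 100_003)
            idx = rng.choice(n, size=keep, replace=False)
            sub = OrdinalDataset(values=data.values[idx], item_codes=data.item_codes,
                                 item_kind=list(data.item_kind),
                                 time_label=data.time_label)
            try:
                net = estimate_network(sub, config)
            except (EstimationError, GlassoError, np.linalg.LinAlgError):
                n_failed += 1
                continue
            sub_vals = _centrality_values(net, metric)
            vals.append(_safe_corr(ref, sub_vals, corr_method))
        if n_failed > MAX_FAILURE_FRACTION * spec.n_boot:
            raise BootstrapError(f"{n_failed}/{spec.n_boot} subset replicates failed at q={q}")
        correlations[float(q)] = np.asarray(vals)

    cs = cs_coefficient(correlations, spec.stability_cor_threshold, spec.stability_prob)
    return StabilityResult(metric=metric,
                           drop_proportions=np.asarray(spec.drop_proportions, dtype=float),
                           correlations=correlations, cs_coefficient=cs,
                           cor_threshold=spec.stability_cor_threshold,
                           prob_threshold=spec.stability_prob)


def _safe_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    """Correlation over nodes; constant vectors yield 0 (no information)."""
    if method == "spearman":
        from scipy.stats import rankdata
        a, b = rankdata(a), rankdata(b)
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _interval_excludes_zero(diff: np.ndarray) -> bool:
    lo, hi = np.quantile(diff, [0.025, 0.975])
    return bool(lo > 0 or hi < 0)


def edge_difference_test(boot: EdgeCITable) -> np.ndarray:
    """Pairwise bootstrapped difference test between all edge weights.

    Entry (a, b) is True when the 95% bootstrap interval of the
    replicate-wise difference between edges a and b excludes zero.  No
    multiplicity correction is applied.
    """
    if boot.replicates is None or boot.replicates.shape[0] < 2:
        raise ValueError("difference tests need >= 2 successful replicates")
    R = boot.replicates
    m = R.shape[1]
    out = np.zeros((m, m), dtype=bool)
    for a in range(m):
        diff = R[:, a:a + 1] - R[:, a:]
        for off, b in enumerate(range(a, m)):
            if b == a:
                continue
            out[a, b] = out[b, a] = _interval_excludes_zero(diff[:, off])
    return out


def centrality_difference_test(boot: EdgeCITable) -> np.ndarray:
    """Pairwise bootstrapped difference test between node strengths."""
    if boot.strength_replicates is None or boot.strength_replicates.shape[0] < 2:
        raise ValueError("difference tests need >= 2 successful replicates")
    S = boot.strength_replicates
    p = S.shape[1]
    out = np.zeros((p, p), dtype=bool)
    for a in range(p):
        for b in range(a + 1, p):
            out[a, b] = out[b, a] = _interval_excludes_zero(S[:, a] - S[:, b])
    return out
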