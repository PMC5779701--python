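"""Permutation-based Network Comparison Test for paired (dependent) data.

Tests whether two networks estimated on the same subjects at two occasions
differ in

* structure — the maximum absolute edge-weight difference M, and
* overall connectivity — the absolute difference in global strength S.

The null hypothesis (both occasions share one network) is simulated by the
standard paired permutation scheme: per subject, with probability 1/2, the
subject's observation vectors are swapped between the two occasions, and
both networks are re-estimated with the identical pipeline (latent
correlations + EBIC-glasso).  p-values use the (1 + k) / (1 + n_perm)
convention, so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlations import EstimationError, OrdinalDataset
from .ggm import GGMConfig, GGMNetwork, GlassoError, estimate_network, global_strength

__all__ = ["NCTResult", "nct_statistics", "nct_dependent"]

MAX_REDRAW_FRACTION = 0.10


class NCTError(RuntimeError):
    """Raised on incompatible inputs or excessive permutation failures."""


@dataclass
class NCTResult:
    """Observed invariance statistics, permutation draws, and p-values."""

    m_observed: float
    s_observed: float
    m_perm: np.ndarray
    s_perm: np.ndarray
    n_perm: int
    paired: bool = True

    @property
    def p_structure(self) -> float:
        return (1.0 + np.sum(self.m_perm >= self.m_observed)) / (1.0 + self.n_perm)

    @property
    def p_strength(self) -> float:
        return (1.0 + np.sum(self.s_perm >= self.s_observed)) / (1.0 + self.n_perm)

    def summary(self) -> dict:
        return {
            "m_observed": self.m_observed,
            "s_observed": self.s_observed,
            "p_structure": self.p_structure,
            "p_strength": self.p_strength,
            "n_perm": self.n_perm,
            "paired": self.paired,
        }


def nct_statistics(net_a: GGMNetwork, net_b: GGMNetwork) -> tuple[float, float]:
    """Invariance statistics (M, S) for two networks on identical nodes."""
    if net_a.node_labels != net_b.node_labels:
        bad = [f"{x}!={y}" for x, y in zip(net_a.node_labels, net_b.node_labels) if x != y]
        raise NCTError("node sets differ: " + (", ".join(bad) or "length mismatch"))
    iu = np.triu_indices(net_a.p, k=1)
    M = float(np.max(np.abs(net_a.W - net_b.W)[iu])) if net_a.p > 1 else 0.0
    S = abs(global_strength(net_a) - global_strength(net_b))
    return M, S


def nct_dependent(
    data_a: OrdinalDataset,
    data_b: OrdinalDataset,
    n_perm: int = 1000,
    config: GGMConfig = GGMConfig(),
    seed: int = 0,
) -> NCTResult:
    """Dependent (paired) Network Comparison Test.

    Both datasets must hold the same subjects in the same order with no
    missing values (the paired design requires complete cases).  Each
    permutation flips, per subject with probability 1/2, which occasion the
    subject's two observation vectors are assigned to; the pipeline is then
    re-run on both permuted datasets with the same configuration.
    Permutations whose estimation fails are redrawn; more than 10% redraws
    aborts.
    """
    if data_a.values.shape != data_b.values.shape:
        raise NCTError("datasets must have identical shape (same subjects, same items)")
    if data_a.item_codes != data_b.item_codes:
        raise NCTError("datasets must share item codes")
    if not np.array_equal(data_a.subject_ids, data_b.subject_ids):
        raise NCTError("datasets must hold the same subjects in the same order")
    if np.isnan(data_a.values).any() or np.isnan(data_b.values).any():
        raise NCTError("paired NCT requires complete cases (no missing values)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    net_a = estimate_network(data_a, config)
    net_b = estimate_network(data_b, config)
    m_obs, s_obs = nct_statistics(net_a, net_b)

    n = data_a.n_subjects
    m_perm = np.empty(n_perm)
    s_perm = np.empty(n_perm)
    rng = np.random.default_rng(seed)
    n_redraws = 0
    b = 0
    while b < n_perm:
        swap = rng.random(n) < 0.5
        va = np.where(swap[:, None], data_b.values, data_a.values)
        vb = np.where(swap[:, None], data_a.values, data_b.values)
        pa = OrdinalDataset(values=va, item_codes=data_a.item_codes,
                            item_kind=list(data_a.item_kind))
        pb = OrdinalDataset(values=vb, item_codes=data_a.item_codes,
                            item_kind=list(data_a.item_kind))
        try:
            pm, ps = nct_statistics(estimate_network(pa, config),
                                    estimate_network(pb, config))
        except (EstimationError, GlassoError, np.linalg.LinAlgError):
            n_redraws += 1
            if n_redraws > MAX_REDRAW_FRACTION * n_perm:
                raise NCTError(f"{n_redraws} permutation redraws exceeded 10% of n_perm")
            continue
        m_perm[b], s_perm[b] = pm, ps
        b += 1

    return NCTResult(m_observed=m_obs, s_observed=s_obs,
                     m_perm=m_perm, s_perm=s_perm, n_perm=n_perm, paired=True)
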