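"""Descriptive cross-wave similarity of estimated networks.

Complements the permutation comparison test with two descriptive measures:

* adjacency correlation — rank (default) or product-moment correlation of
  the lower-triangle edge-weight vectors of two networks, zeros included
  (a regularised network's zeros are estimates, not missing values);
* centrality correlation — correlation of per-node centrality values
  across waves (product-moment by default, matching the "r" convention).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import CentralityTable
from .ggm import GGMNetwork

__all__ = ["adjacency_correlation", "centrality_correlation", "similarity_report"]


def _tri_vector(net: GGMNetwork) -> np.ndarray:
    il = np.tril_indices(net.p, k=-1)
    return net.W[il]


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def adjacency_correlation(net_a: GGMNetwork, net_b: GGMNetwork,
                          method: str = "spearman") -> float:
    """Correlation of the two networks' edge-weight vectors.

    Operates on the lower-triangle off-diagonal entries (zeros included).
    """
    if net_a.node_labels != net_b.node_labels:
        raise ValueError("networks must share node sets and ordering")
    return _corr(_tri_vector(net_a), _tri_vector(net_b), method)


def centrality_correlation(tab_a: CentralityTable, tab_b: CentralityTable,
                           metric: str = "strength",
                           method: str = "pearson") -> float:
    """Correlation of per-node raw centrality values across two waves."""
    if tab_a.node_labels != tab_b.node_labels:
        raise ValueError("centrality tables must share node sets and ordering")
    a = np.asarray(getattr(tab_a, metric), dtype=float)
    b = np.asarray(getattr(tab_b, metric), dtype=float)
    return _corr(a, b, method)


def similarity_report(networks: dict[str, GGMNetwork],
                      centralities: dict[str, CentralityTable] | None = None,
                      metric: str = "strength") -> pd.DataFrame:
    """All pairwise wave similarities as a tidy table.

    One row per unordered wave pair with the adjacency correlation (both
    Spearman and Pearson) and, when centrality tables are supplied, the
    centrality correlation for ``metric``.
    """
    def safe(fn, *args):
        # an empty (all-zero) regularized network leaves the correlation
        # undefined; report NaN rather than aborting the whole study
        try:
            return fn(*args)
        except ValueError:
            return float("nan")

    rows = []
    for wa, wb in combinations(networks.keys(), 2):
        row = {
            "wave_a": wa,
            "wave_b": wb,
            "adjacency_spearman": safe(adjacency_correlation,
                                       networks[wa], networks[wb], "spearman"),
            "adjacency_pearson": safe(adjacency_correlation,
                                      networks[wa], networks[wb], "pearson"),
            "n_entries": networks[wa].p * (networks[wa].p - 1) // 2,
        }
        if centralities is not None:
            row[f"{metric}_correlation"] = safe(
                centrality_correlation, centralities[wa], centralities[wb], metric)
        rows.append(row)
    return pd.DataFrame(rows)
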