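"""Node centrality on weighted partial-correlation networks.

Three standard indices for psychometric networks:

* strength — sum of absolute incident edge weights;
* betweenness — how often a node sits on shortest paths between other
  node pairs (ordered pairs, fractional credit for ties);
* closeness — reciprocal of the summed distance to all other nodes.

Distances are the reciprocal of absolute edge weight (strong edges are
short), the convention of the weighted-network centrality literature;
negative edges enter by magnitude.  Regularised networks can be
disconnected: unreachable pairs get infinite distance, and closeness is
computed over the reachable set scaled by reachable/(p-1) so that values
stay finite and comparable.

Centralities are z-standardised within a network (mean 0, SD 1 with the
n-1 denominator) for cross-wave comparison plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .ggm import EDGE_EPS, GGMNetwork

__all__ = [
    "CentralityTable",
    "node_strength",
    "shortest_path_metrics",
    "centrality_table",
    "standardize",
]


@dataclass
class CentralityTable:
    """Raw and z-standardised centrality indices per node."""

    node_labels: list[str]
    strength: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    z_strength: np.ndarray | None = None
    z_betweenness: np.ndarray | None = None
    z_closeness: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: node, metric, raw, z."""
        rows = []
        for metric in ("strength", "betweenness", "closeness"):
            raw = getattr(self, metric)
            z = getattr(self, f"z_{metric}")
            for i, node in enumerate(self.node_labels):
                rows.append({"node": node, "metric": metric, "raw": raw[i],
                             "z": None if z is None else z[i]})
        return pd.DataFrame(rows)


def node_strength(network: GGMNetwork) -> np.ndarray:
    """Per-node strength: s_i = sum_j |W[i, j]|."""
    return np.abs(network.W).sum(axis=1)


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    A = np.abs(W).copy()
    A[A <= EDGE_EPS] = 0.0
    with np.errstate(divide="ignore"):
        length = np.where(A > 0, 1.0 / A, 0.0)
    return shortest_path(length, method="D", directed=False)


def shortest_path_metrics(network: GGMNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Betweenness and closeness under inverse-absolute-weight distances.

    Betweenness counts ordered source-target pairs (Brandes algorithm with
    fractional credit among equal-length shortest paths); closeness_i is
    (r_i / (p - 1)) / sum of distances to the r_i reachable nodes, which
    reduces to 1 / sum(d) on a connected network.
    """
    p = network.p
    A = np.abs(network.W).copy()
    A[A <= EDGE_EPS] = 0.0

    G = nx.Graph()
    G.add_nodes_from(range(p))
    ii, jj = np.nonzero(np.triu(A, k=1))
    G.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / A[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bet_unordered = nx.betweenness_centrality(G, weight="length", normalized=False)
    # undirected Brandes counts unordered pairs; ordered-pair convention is 2x
    betweenness = 2.0 * np.array([bet_unordered[i] for i in range(p)])

    D = _distance_matrix(network.W)
    closeness = np.zeros(p)
    for i in range(p):
        d = np.delete(D[i], i)
        reach = np.isfinite(d)
        r = int(reach.sum())
        tot = d[reach].sum()
        if r > 0 and tot > 0:
            closeness[i] = (r / (p - 1)) / tot
    return betweenness, closeness


def centrality_table(network: GGMNetwork, standardized: bool = True) -> CentralityTable:
    """Compute all three indices for a network, optionally z-standardised."""
    betweenness, closeness = shortest_path_metrics(network)
    table = CentralityTable(
        node_labels=list(network.node_labels),
        strength=node_strength(network),
        betweenness=betweenness,
        closeness=closeness,
    )
    return standardize(table) if standardized else table


def standardize(table: CentralityTable) -> CentralityTable:
    """z-standardise each metric across the nodes of one network.

    Constant metrics (zero SD) map to all-zero z-scores.
    """
    n = len(table.node_labels)
    if n < 2:
        raise ValueError("standardization requires at least 2 nodes")

    def z(x: np.ndarray) -> np.ndarray:
        # ptp guard: an exactly constant vector can still leave sd at
        # float-noise level, which would blow up the ratio
        sd = np.std(x, ddof=1)
        if sd == 0 or np.ptp(x) == 0:
            return np.zeros_like(x)
        return (x - np.mean(x)) / sd

    table.z_strength = z(table.strength)
    table.z_betweenness = z(table.betweenness)
    table.z_closeness = z(table.closeness)
    return table
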