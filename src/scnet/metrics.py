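"""Nodal and global graph metrics for binary structural covariance networks.

Conventions (stated because several are genuine choices):

* Degree ``k_i`` is the row sum of the adjacency matrix.
* Clustering ``C_i = 2 e_i / (k_i (k_i - 1))`` with ``C_i := 0`` when
  ``k_i < 2`` (the ratio is 0/0 there); the network clustering coefficient
  ``C`` averages ``C_i`` over *all* N nodes.
* Nodal path length ``L_i`` is the mean BFS distance from i to the nodes it
  can reach; unreachable pairs are excluded rather than imputed, and their
  count is always reported. ``L`` is the mean of ``L_i`` over nodes with at
  least one reachable partner. ``divide_by_n=True`` instead divides
  each node's distance sum by N (a printed-formula variant that understates
  L by (N-1)/N on a connected graph).
* Betweenness ``BC_i`` sums, over unordered node pairs excluding i, the
  fraction of their shortest paths passing through i (fractional counting
  of tied geodesics). Normalized betweenness ``bc_i = BC_i / mean(BC)``;
  hubs are nodes with ``bc_i > 2`` (strict). When every BC is zero
  (e.g. complete graphs) bc is undefined and no node is a hub.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .network import BinaryGraph

__all__ = [
    "degree",
    "clustering",
    "path_length",
    "betweenness",
    "identify_hubs",
    "node_metrics",
    "global_metrics",
    "PathLengthResult",
    "GlobalMetrics",
]


def _adj(g: BinaryGraph | np.ndarray) -> np.ndarray:
    return g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)


def degree(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Number of links per node: k_i = sum_j a_ij."""
    return _adj(g).sum(axis=1).astype(int)


def clustering(g: BinaryGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean over all nodes.

    e_i (edges among i's neighbours) is half the number of length-3 closed
    walks through i, i.e. diag(A^3)/2.
    """
    a = _adj(g).astype(float)
    k = a.sum(axis=1)
    e = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    c = np.divide(2.0 * e, denom, out=np.zeros_like(e), where=denom > 0)
    return c, float(c.mean())


@dataclass
class PathLengthResult:
    per_node: np.ndarray  # L_i; NaN for isolated nodes
    global_L: float
    unreachable_pairs: int  # unordered pairs with no connecting path
    connected: bool


def path_length(
    g: BinaryGraph | np.ndarray, divide_by_n: bool = False
) -> PathLengthResult:
    """BFS shortest-path lengths, summarized per node and globally.

    Raises
    ------
    ValueError
        If the graph has no reachable pair at all (edgeless graph).
    """
    a = _adj(g)
    n = a.shape[0]
    d = shortest_path(a.astype(float), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    reach_counts = finite.sum(axis=1)
    if reach_counts.sum() == 0:
        raise ValueError("graph has no connected node pair; path length undefined")
    sums = np.where(finite, d, 0.0).sum(axis=1)
    denom = np.full(n, float(n)) if divide_by_n else reach_counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_node = np.where(reach_counts > 0, sums / denom, np.nan)
    global_l = float(np.nanmean(per_node))
    unreachable = int((off & ~finite).sum()) // 2
    return PathLengthResult(per_node, global_l, unreachable, unreachable == 0)


def betweenness(g: BinaryGraph | np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Betweenness centrality BC_i and normalized bc_i = BC_i / mean(BC).

    Fractional (Brandes) counting over unordered pairs, endpoints excluded.
    Returns ``(BC, bc)``; ``bc`` is None when mean(BC) = 0.
    """
    a = _adj(g)
    gx = nx.from_numpy_array(a)
    bc_dict = nx.betweenness_centrality(gx, normalized=False)
    bc = np.array([bc_dict[i] for i in range(a.shape[0])])
    mean_bc = bc.mean()
    if mean_bc <= 0:
        return bc, None
    return bc, bc / mean_bc


def identify_hubs(
    g: BinaryGraph | np.ndarray, labels: list[str] | None = None
) -> list[str]:
    """Nodes whose normalized betweenness strictly exceeds 2."""
    a = _adj(g)
    if labels is None:
        labels = g.labels if isinstance(g, BinaryGraph) else [
            f"R{i + 1:03d}" for i in range(a.shape[0])
        ]
    _, bc = betweenness(a)
    if bc is None:
        return []
    return [labels[i] for i in np.nonzero(bc > 2)[0]]


@dataclass
class GlobalMetrics:
    clustering: float
    path_length: float
    n_edges: int
    connected: bool
    unreachable_pairs: int


def node_metrics(g: BinaryGraph, divide_by_n: bool = False) -> pd.DataFrame:
    """Tidy per-node table: degree, clustering, path length, betweenness, hub."""
    k = degree(g)
    c, _ = clustering(g)
    try:
        pl = path_length(g, divide_by_n).per_node
    except ValueError:
        pl = np.full(g.n_nodes, np.nan)
    bc, bc_norm = betweenness(g)
    hubs = np.zeros(g.n_nodes, dtype=bool)
    if bc_norm is not None:
        hubs = bc_norm > 2
    return pd.DataFrame(
        {
            "node": g.labels,
            "degree": k,
            "clustering": c,
            "path_length": pl,
            "betweenness": bc,
            "betweenness_norm": bc_norm if bc_norm is not None else np.nan,
            "hub": hubs,
        }
    )


def global_metrics(g: BinaryGraph, divide_by_n: bool = False) -> GlobalMetrics:
    """Network-level clustering coefficient and characteristic path length."""
    _, c = clustering(g)
    pl = path_length(g, divide_by_n)
    return GlobalMetrics(c, pl.global_L, g.n_edges, pl.connected, pl.unreachable_pairs)
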