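"""Association matrices and sparsity-thresholded binary graphs.

The group-level network is built in three steps:

1. **Shrunk covariance.** With few subjects (n ~ 36) and many regions
   (p = 148) the sample covariance is singular, so the estimate is shrunk
   toward the scaled identity: ``Sigma = (1 - a) S + a mu I`` with
   ``mu = trace(S)/p`` and the analytically optimal intensity ``a`` of
   Ledoit & Wolf (minimizing expected Frobenius loss), clipped to [0, 1].
2. **Partial correlation.** With precision ``Omega = Sigma^-1``,
   ``pcor_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`` — the correlation of
   regions i and j after removing the linear influence of all others.
3. **Binarization.** At sparsity ``s`` the strongest
   ``floor(s * p(p-1)/2)`` connections (by |pcor|, signed optional) become
   edges of an undirected, unweighted graph; a sweep over s in [0.05, 0.35]
   (step 0.01) yields a nested family of 31 graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cohort import ResidualMatrix

__all__ = [
    "AssociationMatrix",
    "BinaryGraph",
    "ledoit_wolf_covariance",
    "partial_correlation",
    "binarize_at_sparsity",
    "sparsity_sweep",
    "sparsity_grid",
]


def ledoit_wolf_covariance(
    residuals: ResidualMatrix | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf shrunk covariance of (already centered) residuals.

    Returns ``(Sigma, a)`` where ``Sigma = (1 - a) S + a mu I``, ``S`` is
    the sample covariance (1/n convention), ``mu = trace(S)/p`` and ``a``
    is the optimal shrinkage intensity clipped to [0, 1]. For degenerate
    all-constant input (S proportional to a zero target distance) the
    intensity is reported as 0 with a warning and ``S`` is returned as-is.
    """
    x = residuals.values if isinstance(residuals, ResidualMatrix) else residuals
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects to estimate covariance")
    x = x - x.mean(axis=0)  # residuals are centered already; harmless otherwise

    s = x.T @ x / n
    mu = np.trace(s) / p
    # squared norms under <A,B> = trace(A B')/p
    delta2 = np.sum((s - mu * np.eye(p)) ** 2) / p
    if delta2 <= np.finfo(float).tiny:
        warnings.warn(
            "sample covariance equals the shrinkage target (zero-variance "
            "input?); shrinkage intensity reported as 0",
            stacklevel=2,
        )
        return s, 0.0
    sq_norms = np.einsum("ij,ij->i", x, x)  # ||x_k||^2 per subject
    beta2 = np.sum(sq_norms**2) / (n**2 * p) - np.sum(s**2) / (n * p)
    beta2 = min(max(beta2, 0.0), delta2)
    a = beta2 / delta2
    sigma = (1.0 - a) * s + a * mu * np.eye(p)
    return sigma, float(a)


@dataclass
class AssociationMatrix:
    """Symmetric region x region partial-correlation matrix for one group."""

    values: np.ndarray
    labels: list[str]
    shrinkage: float = float("nan")
    group: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def partial_correlation(
    sigma: np.ndarray,
    labels: list[str] | None = None,
    shrinkage: float = float("nan"),
    group: str = "",
) -> AssociationMatrix:
    """Partial correlations from a (shrunk) covariance matrix.

    Inverts ``sigma`` to the precision ``Omega`` and standardizes its
    negated off-diagonals; the diagonal is set to 1 by convention.
    """
    sigma = np.asarray(sigma, dtype=float)
    p = sigma.shape[0]
    try:
        omega = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; inspect the shrinkage intensity "
            "(a > 0 guarantees invertibility for non-degenerate input)"
        ) from err
    d = np.sqrt(np.diag(omega))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise np.linalg.LinAlgError(
            "precision matrix has non-positive diagonal; covariance was not "
            "positive definite — increase shrinkage"
        )
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2  # enforce exact symmetry
    np.fill_diagonal(pcor, 1.0)
    if labels is None:
        labels = [f"R{i + 1:03d}" for i in range(p)]
    return AssociationMatrix(pcor, list(labels), shrinkage, group)


@dataclass
class BinaryGraph:
    """Undirected unweighted graph at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    labels: list[str] = field(default_factory=list)
    group: str = ""
    measure: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)
        if not self.labels:
            self.labels = [f"R{i + 1:03d}" for i in range(a.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        nx.relabel_nodes(g, dict(enumerate(self.labels)), copy=False)
        return g


def _edge_budget(n_nodes: int, s: float) -> int:
    total = n_nodes * (n_nodes - 1) // 2
    # tiny epsilon absorbs float error when s*total is mathematically integral
    return int(np.floor(s * total + 1e-9))


def _ranked_pairs(assoc: AssociationMatrix, rank_by: str) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(assoc.n_regions, 1)
    w = assoc.values[iu, ju]
    key = np.abs(w) if rank_by == "absolute" else w
    # strongest first; ties broken by lexicographically smaller (i, j)
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order]


def binarize_at_sparsity(
    assoc: AssociationMatrix,
    s: float,
    rank_by: str = "absolute",
    measure: str = "",
) -> BinaryGraph:
    """Keep the strongest fraction ``s`` of connections as binary edges.

    ``rank_by='absolute'`` (default) ranks by |partial correlation|;
    ``'positive'`` ranks by the signed value, so strong negative partials
    are never selected. The edge budget is ``floor(s * p(p-1)/2)``; ties at
    the cutoff resolve to the lexicographically smaller region pair, making
    the graph a deterministic function of the association matrix.
    """
    if rank_by not in ("absolute", "positive"):
        raise ValueError("rank_by must be 'absolute' or 'positive'")
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must lie in (0, 1]; got {s}")
    n = assoc.n_regions
    m = _edge_budget(n, s)
    if m < 1:
        raise ValueError(
            f"sparsity {s} yields zero edges for {n} nodes; below the "
            "estimable range"
        )
    iu, ju = _ranked_pairs(assoc, rank_by)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:m], ju[:m]] = 1
    adj |= adj.T
    return BinaryGraph(adj, s, list(assoc.labels), assoc.group, measure)


def sparsity_grid(s_min: float = 0.05, s_max: float = 0.35, step: float = 0.01) -> np.ndarray:
    """The sparsity sweep values (inclusive of both ends; 31 for defaults)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    return np.round(np.arange(s_min, s_max + step / 2, step), 10)


def sparsity_sweep(
    assoc: AssociationMatrix,
    s_min: float = 0.05,
    s_max: float = 0.35,
    step: float = 0.01,
    rank_by: str = "absolute",
    measure: str = "",
) -> list[BinaryGraph]:
    """Binarize across the sparsity grid; edge sets are nested in s."""
    return [
        binarize_at_sparsity(assoc, float(s), rank_by, measure)
        for s in sparsity_grid(s_min, s_max, step)
    ]
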