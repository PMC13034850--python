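"""Neighborhood graphs and affinity kernels on the original data space.

Every downstream diagnostic (metric estimation, fragmentation screening)
consumes the same substrate built here: a symmetric sparse matrix ``A`` of
exact Euclidean distances between neighboring points, optionally weighted
into an affinity matrix ``K`` by a Gaussian or binary kernel.

Search is exact (block-wise, so memory stays bounded at desk scale) and
ties at equal distance are resolved in favor of the lower sample index, so
graph construction is deterministic and independent of input ordering.
Approximate indices for n >> 1e5 are out of scope; swapping the block-wise
search for an ANN index is the documented plug-in point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "PointSet",
    "Embedding",
    "NeighborGraph",
    "AffinityMatrix",
    "build_knn_graph",
    "build_radius_graph",
    "gaussian_kernel",
    "binary_kernel",
    "select_epsilon",
    "minimal_connecting_radius",
    "graph_to_edge_table",
]


def _as_finite_2d(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {X.shape}")
    if X.shape[0] < 1:
        raise ValueError(f"{name} must contain at least one row")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite entries")
    return X


@dataclass
class PointSet:
    """Original data: ``n`` samples in ``D``-dimensional feature space.

    Parameters
    ----------
    X : (n, D) array
        Coordinates, arbitrary units; must be finite.
    sample_ids : sequence of str, optional
        Unique identifiers; defaults to ``"s0" .. "s{n-1}"``.
    labels : sequence, optional
        Per-sample categorical tags (e.g. mixture component, cell type).
    """

    X: np.ndarray
    sample_ids: list[str] = field(default=None)
    labels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.X = _as_finite_2d(self.X, "X")
        n = self.X.shape[0]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length does not match X")
            if len(set(self.sample_ids)) != n:
                raise ValueError("sample_ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


@dataclass
class Embedding:
    """Low-dimensional coordinates ``Y`` paired with a :class:`PointSet`."""

    Y: np.ndarray

    def __post_init__(self):
        self.Y = _as_finite_2d(self.Y, "Y")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def d(self) -> int:
        return self.Y.shape[1]

    def diameter(self) -> float:
        """Largest pairwise distance, used to set default bandwidths."""
        lo, hi = self.Y.min(axis=0), self.Y.max(axis=0)
        # cheap bound is enough for bandwidth defaults at large n
        if self.n > 4000:
            return float(np.linalg.norm(hi - lo))
        return float(cdist(self.Y, self.Y).max())


@dataclass
class NeighborGraph:
    """Symmetric neighborhood graph with stored Euclidean distances.

    ``A`` holds one entry per (directed) stored edge; an absent entry means
    "not neighbors" (conceptually infinite distance).  Self-edges are
    implicit: they are never stored in ``A`` but counted by
    :meth:`degrees` when ``includes_self`` is true.
    """

    A: sp.csr_matrix
    kind: str  # {"knn", "radius"}
    k: int = None
    r: float = None
    includes_self: bool = True

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        """Indices of the neighbors of ``i`` (self excluded)."""
        return self.A.indices[self.A.indptr[i]: self.A.indptr[i + 1]]

    def degrees(self) -> np.ndarray:
        """Neighbor counts |N_i| (self counted when ``includes_self``)."""
        deg = np.diff(self.A.indptr)
        return deg + 1 if self.includes_self else deg

    def neighborhood_radii(self) -> np.ndarray:
        """Per-point largest stored neighbor distance (0 for isolated)."""
        out = np.zeros(self.n)
        for i in range(self.n):
            row = self.A.data[self.A.indptr[i]: self.A.indptr[i + 1]]
            if row.size:
                out[i] = row.max()
        return out

    def n_components(self) -> int:
        ncomp, _ = connected_components(self.A, directed=False)
        return int(ncomp)


@dataclass
class AffinityMatrix:
    """Sparse kernel matrix ``K`` in [0, 1] over a neighborhood graph."""

    K: sp.csr_matrix
    epsilon: float  # kernel width; for binary kernels, the graph radius
    kernel_kind: str  # {"gaussian", "binary"}

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.K.sum(axis=1)).ravel()


def _pairwise_block(X: np.ndarray, block: int = 1024):
    """Yield (row range, distance block) without forming the full matrix."""
    n = X.shape[0]
    for start in range(0, n, block):
        stop = min(start + block, n)
        yield start, stop, cdist(X[start:stop], X)


def build_knn_graph(points: PointSet, k: int) -> NeighborGraph:
    """Symmetrized k-nearest-neighbor graph with exact distances.

    The neighbor list of each point contains itself plus its k-1 nearest
    other points (ties broken toward the lower index); the union
    symmetrization then guarantees every degree lies in [k, 2k-1]
    counting self.
    """
    X = points.X
    n = X.shape[0]
    if not isinstance(k, (int, np.integer)) or k <= 1:
        raise ValueError(f"k must be an integer > 1, got {k!r}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points n={n}")
    # collect undirected edges in a dict so zero-distance edges between
    # duplicate points survive (sparse maximum() would silently drop them)
    edges: dict = {}
    for start, stop, D in _pairwise_block(X):
        for loc in range(stop - start):
            i = start + loc
            d = D[loc]
            # lexicographic (distance, index) sort: deterministic ties
            order = np.lexsort((np.arange(n), d))
            # drop self explicitly (with duplicates, the lowest-index zero
            # is not guaranteed to be i itself)
            sel = order[order != i][: k - 1]
            for j in sel:
                edges[(min(i, int(j)), max(i, int(j)))] = d[j]
    rows = np.empty(2 * len(edges), dtype=int)
    cols = np.empty(2 * len(edges), dtype=int)
    vals = np.empty(2 * len(edges))
    for pos, ((a, b), dist) in enumerate(edges.items()):
        rows[2 * pos], cols[2 * pos], vals[2 * pos] = a, b, dist
        rows[2 * pos + 1], cols[2 * pos + 1], vals[2 * pos + 1] = b, a, dist
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A.sort_indices()
    return NeighborGraph(A=A, kind="knn", k=int(k), includes_self=True)


def build_radius_graph(points: PointSet, r: float) -> NeighborGraph:
    """Radius-neighbor graph: edge (i, i') stored iff ||x_i - x_i'|| <= r."""
    if not np.isfinite(r) or r <= 0:
        raise ValueError(f"radius must be positive, got {r!r}")
    X = points.X
    n = X.shape[0]
    rows, cols, vals = [], [], []
    for start, stop, D in _pairwise_block(X):
        sub = D <= r
        np.fill_diagonal(sub[:, start:stop], False)
        ii, jj = np.nonzero(sub)
        rows.extend(ii + start)
        cols.extend(jj)
        vals.extend(D[ii, jj])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    A.sort_indices()
    graph = NeighborGraph(A=A, kind="radius", r=float(r), includes_self=True)
    if graph.n_components() > 1:
        warnings.warn(
            f"radius graph with r={r:g} is disconnected "
            f"({graph.n_components()} components)",
            stacklevel=2,
        )
    return graph


def gaussian_kernel(graph: NeighborGraph, epsilon: float) -> AffinityMatrix:
    """Gaussian affinities K_ii' = exp(-A_ii'^2 / eps^2) on stored edges.

    Off-graph entries are exactly zero and self-affinities are 1.  When the
    graph is a radius graph whose radius falls outside the conventional
    [3 eps, 10 eps] band, a warning is logged: the truncation then either
    clips non-negligible kernel mass (r < 3 eps) or stores numerically
    irrelevant edges (r > 10 eps).
    """
    if not np.isfinite(epsilon) or epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon!r}")
    if graph.kind == "radius" and not (
            3 * epsilon * (1 - 1e-12) <= graph.r <= 10 * epsilon * (1 + 1e-12)):
        logger.warning(
            "radius r=%g outside the recommended [3*eps, 10*eps] band for eps=%g",
            graph.r, epsilon,
        )
    K = graph.A.copy().astype(float)
    K.data = np.exp(-(K.data ** 2) / epsilon ** 2)
    if graph.includes_self:
        K = (K + sp.eye(graph.n, format="csr")).tocsr()
    K.sort_indices()
    return AffinityMatrix(K=K, epsilon=float(epsilon), kernel_kind="gaussian")


def binary_kernel(graph: NeighborGraph) -> AffinityMatrix:
    """0/1 affinities: 1 on stored edges (and self), 0 elsewhere."""
    K = graph.A.copy().astype(float)
    K.data = np.ones_like(K.data)
    if graph.includes_self:
        K = (K + sp.eye(graph.n, format="csr")).tocsr()
    K.sort_indices()
    eps = graph.r if graph.kind == "radius" else float("nan")
    return AffinityMatrix(K=K, epsilon=eps, kernel_kind="binary")


def select_epsilon(points: PointSet, k: int, tolerance: float = None) -> float:
    """Choose the Gaussian kernel width matching a k-NN neighborhood scale.

    Returns eps such that the mean row sum of the Gaussian kernel over a
    radius graph with r = 3 eps is within ``tolerance`` of ``k`` (default
    tolerance 0.05 k).  The mean row sum increases monotonically with eps,
    so a bisection on log eps between the smallest nonzero nearest-neighbor
    distance and the data diameter brackets the solution.
    """
    if not isinstance(k, (int, np.integer)) or k <= 1:
        raise ValueError(f"k must be an integer > 1, got {k!r}")
    if tolerance is None:
        tolerance = 0.05 * k
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    X = points.X
    # bracket endpoints
    nn_d = np.full(points.n, np.inf)
    diam = 0.0
    for start, stop, D in _pairwise_block(X):
        np.fill_diagonal(D[:, start:stop], np.inf)
        nn_d[start:stop] = D.min(axis=1)
        D[~np.isfinite(D)] = 0.0
        diam = max(diam, D.max())
    pos = nn_d[np.isfinite(nn_d) & (nn_d > 0)]
    if pos.size == 0 or diam <= 0:
        raise ValueError("degenerate data: all points coincide")
    lo, hi = float(pos.min()), float(diam)

    def mean_row_sum(eps: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # disconnected brackets are fine
            graph = build_radius_graph(points, 3 * eps)
        return float(gaussian_kernel(graph, eps).row_sums().mean())

    f_lo, f_hi = mean_row_sum(lo), mean_row_sum(hi)
    if f_lo > k + tolerance or f_hi < k - tolerance:
        raise RuntimeError(
            "no epsilon in the search bracket achieves the target row sum: "
            f"mean row sum at eps={lo:g} is {f_lo:g}, at eps={hi:g} is {f_hi:g}, "
            f"target {k} +/- {tolerance:g}"
        )
    llo, lhi = np.log(lo), np.log(hi)
    eps = np.exp(0.5 * (llo + lhi))
    for _ in range(80):
        eps = np.exp(0.5 * (llo + lhi))
        rs = mean_row_sum(eps)
        if abs(rs - k) <= tolerance:
            break
        if rs < k:
            llo = np.log(eps)
        else:
            lhi = np.log(eps)
    return float(eps)


def minimal_connecting_radius(points: PointSet) -> float:
    """Smallest radius at which the radius graph is connected.

    This is the largest edge of the Euclidean minimum spanning tree — a
    data statistic useful for choosing radius grids whose smallest cell
    still yields a connected graph.  O(n^2) memory; desk scale only.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import pdist, squareform

    if points.n < 2:
        return 0.0
    D = squareform(pdist(points.X))
    mst = minimum_spanning_tree(sp.csr_matrix(D))
    return float(mst.data.max())


def graph_to_edge_table(graph: NeighborGraph, kernel: AffinityMatrix = None):
    """Sparse edge list as a DataFrame: i, j, distance, affinity."""
    import pandas as pd

    coo = sp.triu(graph.A, k=1).tocoo()
    rec = {"i": coo.row, "j": coo.col, "distance": coo.data}
    if kernel is not None:
        K = kernel.K.tocsr()
        rec["affinity"] = np.asarray(
            [K[i, j] for i, j in zip(coo.row, coo.col)], dtype=float
        )
    return pd.DataFrame(rec)
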