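"""Local and global isometrization of an embedding, and link geometry.

Given the field of distortion matrices H, a neighborhood of a query point
``m`` can be re-drawn so that it becomes locally distortion-free.  The
machinery is three kernels-and-matrices steps:

* ``H*`` — a kernel-weighted average of the per-point H around ``m``
  (averaging bandwidth ``eps2``);
* the exact transform ``y -> (H*)^p (y - m) + m`` with exponent
  ``p in {-1, -1/2}``;
* a smooth interpolation between the original and transformed coordinates,
  weighted by a second kernel around ``m`` (interpolation bandwidth
  ``eps1``), so the correction fades out away from the query.

Because the eigenvalues of H carry *squared* stretch, the exponent -1/2 is
the distance-correcting choice and the default; -1 applies the full inverse
metric and overcorrects distances (it is retained because both conventions
appear in practice).  All kernels are Gaussian, exp(-||u - v||^2 / eps^2).

The link-selection geometry behind focus-plus-context views is pure
filtering: edges from flagged fragmentation centers within a screen radius
of the query to their nearest original-space neighbors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragmentation import FragmentationResult
from .graphs import Embedding, NeighborGraph
from .rmetric import LocalMetricField

__all__ = [
    "IsometrizeView",
    "LinkSet",
    "local_average_metric",
    "isometrize_at",
    "global_isometrize",
    "neighborhood_links",
    "export_corrected",
    "linkset_json",
]


def _gauss(U: np.ndarray, m: np.ndarray, eps: float) -> np.ndarray:
    return np.exp(-np.sum((U - m) ** 2, axis=-1) / eps ** 2)


def _matrix_power(H: np.ndarray, p: float, regularize: bool = False) -> np.ndarray:
    """Symmetric matrix power via eigendecomposition; optionally ridge-fix."""
    w, v = np.linalg.eigh(H)
    if np.any(w <= 0):
        if not regularize:
            raise ValueError("matrix is not positive-definite")
        warnings.warn("singular H*; regularizing eigenvalues before inversion")
        w = np.maximum(w, 1e-10 * max(w.max(), 1.0))
    return (v * w ** p) @ v.T


@dataclass
class IsometrizeView:
    """A frozen-or-live local isometrization around a query point."""

    m: np.ndarray
    eps1: float
    eps2: float
    exponent: float
    H_star: np.ndarray
    weights: np.ndarray  # averaging weights, sum to 1
    Y_tilde: np.ndarray  # fully transformed coordinates
    Y_out: np.ndarray    # interpolated output coordinates
    frozen: bool = False

    def freeze(self) -> "IsometrizeView":
        self.frozen = True
        return self


@dataclass
class LinkSet:
    """Edges to draw for one focus-plus-context query."""

    m: np.ndarray
    delta: float
    k: int
    edges: list  # [(center, neighbor), ...]


def local_average_metric(
    field: LocalMetricField, embedding: Embedding, m, eps2: float,
):
    """Kernel-weighted average H* = sum_j w_j H_j around the query m.

    Weights are the normalized Gaussian similarities of the embedded points
    to ``m`` with bandwidth eps2.  If every kernel value underflows to zero
    the nearest point's H is returned with a warning.
    """
    if eps2 <= 0:
        raise ValueError(f"eps2 must be positive, got {eps2!r}")
    m = np.asarray(m, dtype=float)
    w = _gauss(embedding.Y, m, eps2)
    total = w.sum()
    if total == 0:
        warnings.warn("all averaging weights underflow; nearest-point fallback")
        j = int(np.argmin(np.linalg.norm(embedding.Y - m, axis=1)))
        w = np.zeros(embedding.n)
        w[j] = 1.0
    else:
        w = w / total
    if np.all(field.H == field.H[0]):
        # convex combination of identical matrices: return it exactly,
        # so an identity field yields an exactly-identity transform
        return field.H[0].copy(), w
    H_star = np.einsum("j,jkl->kl", w, field.H)
    return H_star, w


def isometrize_at(
    embedding: Embedding, field: LocalMetricField, m,
    eps1: float = None, eps2: float = None, exponent: float = -0.5,
) -> tuple[np.ndarray, IsometrizeView]:
    """Smoothly isometrize the embedding around the query point m.

    Default bandwidths are 0.1 x the embedding diameter — visually local.
    Returns the interpolated coordinates together with the full view state.
    """
    if exponent not in (-1.0, -0.5):
        raise ValueError("exponent must be -1 or -1/2")
    m = np.asarray(m, dtype=float)
    if eps1 is None or eps2 is None:
        scale = 0.1 * embedding.diameter()
        eps1 = scale if eps1 is None else eps1
        eps2 = scale if eps2 is None else eps2
    if eps1 <= 0:
        raise ValueError(f"eps1 must be positive, got {eps1!r}")
    H_star, w_avg = local_average_metric(field, embedding, m, eps2)
    T = _matrix_power(H_star, float(exponent), regularize=True)
    Y = embedding.Y
    if np.array_equal(T, np.eye(embedding.d)):
        Y_tilde = Y.copy()  # exact identity; avoid re-centering round-off
    else:
        Y_tilde = (Y - m) @ T.T + m
    w1 = _gauss(Y, m, eps1)[:, None]
    if Y_tilde is not Y and np.array_equal(Y_tilde, Y):
        Y_out = Y.copy()  # interpolating between equal endpoints is exact
    else:
        Y_out = w1 * Y_tilde + (1.0 - w1) * Y
    view = IsometrizeView(
        m=m, eps1=float(eps1), eps2=float(eps2), exponent=float(exponent),
        H_star=H_star, weights=w_avg, Y_tilde=Y_tilde, Y_out=Y_out,
    )
    return Y_out, view


def global_isometrize(embedding: Embedding, H_ref: np.ndarray, exponent: float = -0.5) -> Embedding:
    """Map every coordinate through (H_ref)^exponent about the origin."""
    if exponent not in (-1.0, -0.5):
        raise ValueError("exponent must be -1 or -1/2")
    H_ref = np.asarray(H_ref, dtype=float)
    T = _matrix_power(H_ref, float(exponent), regularize=False)
    return Embedding(Y=embedding.Y @ T.T)


def neighborhood_links(
    result: FragmentationResult, graph: NeighborGraph, embedding: Embedding,
    m, delta: float, k: int,
) -> LinkSet:
    """Edges for a focus-plus-context query at m.

    A (center, neighbor) edge is listed iff the center is a flagged
    fragmentation center lying within ``delta`` of ``m`` in embedding
    coordinates, and the neighbor is among the center's ``k`` nearest
    stored original-space neighbors (ties toward the lower index).
    """
    if delta < 0:
        raise ValueError(f"delta must be nonnegative, got {delta!r}")
    m = np.asarray(m, dtype=float)
    close = np.linalg.norm(embedding.Y - m, axis=1) <= delta
    edges = []
    for i in np.nonzero(result.flagged & close)[0]:
        nbrs = graph.neighbors(i)
        dists = graph.A.data[graph.A.indptr[i]: graph.A.indptr[i + 1]]
        order = np.lexsort((nbrs, dists))[:k]
        edges.extend((int(i), int(nbrs[o])) for o in order)
    return LinkSet(m=m, delta=float(delta), k=int(k), edges=edges)


def export_corrected(view: IsometrizeView, field: LocalMetricField,
                     sample_ids=None, axis_scale: str = "sqrt_lambda") -> pd.DataFrame:
    """Corrected coordinates plus ellipse geometry for a frozen view.

    Columns: id, x, y, angle, size1, size2 — the view's output coordinates
    and the per-point ellipse orientation/semi-axes of the metric field.
    Round-trips losslessly through ``DataFrame.to_csv`` at default precision.
    """
    if not view.frozen:
        raise RuntimeError("view must be frozen before export (call .freeze())")
    if field.d != 2:
        raise ValueError("export_corrected renders d = 2 views")
    n = field.n
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    axes = field.stretches() if axis_scale == "sqrt_lambda" else field.lam
    return pd.DataFrame({
        "id": list(sample_ids),
        "x": view.Y_out[:, 0],
        "y": view.Y_out[:, 1],
        "angle": field.major_angles(),
        "size1": axes[:, 0],
        "size2": axes[:, 1],
    })


def linkset_json(links: LinkSet) -> str:
    return json.dumps({
        "m": [float(x) for x in links.m],
        "delta": links.delta,
        "k": links.k,
        "edges": [[int(a), int(b)] for a, b in links.edges],
    }, indent=2)
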