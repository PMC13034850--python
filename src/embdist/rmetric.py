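"""Per-point distortion matrices from a graph Laplacian and an embedding.

The estimator attaches to every embedded point ``y_i`` a symmetric
positive-semidefinite d x d matrix ``H_i`` — the dual of the embedding's
pushforward Riemannian metric.  Its eigenvectors are the principal
directions of distortion and its eigenvalues ``lambda_j`` carry the
*squared* linear stretch in those directions: an embedding that dilates one
axis by a factor s produces ``lambda = s**2`` along it, and an isometric
embedding gives ``H_i = I`` everywhere.  The inverse ``G_i = H_i^{-1}`` is
the pushforward metric itself, i.e. the local correction that restores
original-space distance computations in embedding coordinates.

The construction is in two steps.  First a *geometric* graph Laplacian is
built from the affinity kernel: the kernel is density-renormalized
(``W = D^-1 K D^-1``), row-normalized to a Markov matrix ``P``, and scaled,

    L = (4 / eps^2) (P - I),

which converges to the Laplace-Beltrami operator of the sampled manifold
independently of the sampling density.  Second, ``H_i`` is read off L by the
centered second-moment (carre du champ) identity

    H_i[k, l] = 1/2 * sum_j L[i, j] (y_j[k] - y_i[k]) (y_j[l] - y_i[l]),

which is the Laplacian applied to products of centered coordinates and is
numerically stabler than forming L(y_k y_l) term by term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graphs import AffinityMatrix, Embedding

__all__ = [
    "LaplacianOperator",
    "LocalMetricField",
    "geometric_laplacian",
    "local_distortions",
    "truncate_singular_values",
    "normalize_metrics",
    "condition_numbers",
    "metric_table",
]

#: eigenvalues below this floor are treated as zero when inverting H
PINV_FLOOR = 1e-10


@dataclass
class LaplacianOperator:
    """Sparse geometric graph Laplacian; rows sum to zero."""

    L: sp.csr_matrix
    rescale_epsilon: float
    normalization: str = "geometric"

    @property
    def n(self) -> int:
        return self.L.shape[0]


def geometric_laplacian(kernel: AffinityMatrix, rescale_epsilon: float) -> LaplacianOperator:
    """Density-renormalized ("geometric") graph Laplacian.

    Parameters
    ----------
    kernel : AffinityMatrix
        Symmetric nonnegative affinities with strictly positive row sums.
    rescale_epsilon : float
        The bandwidth entering the 4/eps^2 scaling.  Matching it to the
        kernel width makes the estimator consistent (H -> I on isometries);
        it is exposed separately because published analyses also treat it
        as a free rescaling of the output.
    """
    if not np.isfinite(rescale_epsilon) or rescale_epsilon <= 0:
        raise ValueError(f"rescale_epsilon must be positive, got {rescale_epsilon!r}")
    K = kernel.K.tocsr()
    if (K != K.T).nnz != 0:
        raise ValueError("kernel matrix must be symmetric")
    if K.nnz and K.data.min() < 0:
        raise ValueError("kernel matrix must be nonnegative")
    deg = np.asarray(K.sum(axis=1)).ravel()
    dead = np.nonzero(deg <= 0)[0]
    if dead.size:
        raise ValueError(
            f"isolated node(s) with zero kernel row sum: {dead[:10].tolist()}"
        )
    Dinv = sp.diags(1.0 / deg)
    W = Dinv @ K @ Dinv  # density renormalization, alpha = 1
    rs = np.asarray(W.sum(axis=1)).ravel()
    P = sp.diags(1.0 / rs) @ W
    L = (P - sp.eye(K.shape[0], format="csr")) * (4.0 / rescale_epsilon ** 2)
    return LaplacianOperator(L=L.tocsr(), rescale_epsilon=float(rescale_epsilon))


@dataclass
class LocalMetricField:
    """Spectrally decomposed distortion matrices for every sample.

    Attributes
    ----------
    H : (n, d, d) array
        Dual pushforward metric (distortion) per point; symmetric PSD.
    lam : (n, d) array
        Eigenvalues of H, sorted descending.
    V : (n, d, d) array
        Matching orthonormal eigenvectors in columns.
    G : (n, d, d) array
        Pseudo-inverse of H with eigenvalue floor ``PINV_FLOOR`` — the
        pushforward metric (local correction).
    cap : float or None
        Truncation bound applied to ``lam`` (None if untruncated).
    scale_factor : float
        Global divisor applied by :func:`normalize_metrics` (1.0 if none).
    n_truncated : int
        Number of samples whose eigenvalues were clipped by the cap.
    """

    H: np.ndarray
    lam: np.ndarray
    V: np.ndarray
    G: np.ndarray
    cap: float = None
    scale_factor: float = 1.0
    n_truncated: int = 0

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def d(self) -> int:
        return self.H.shape[1]

    def stretches(self) -> np.ndarray:
        """Per-direction linear stretch sqrt(lambda), (n, d)."""
        return np.sqrt(np.maximum(self.lam, 0.0))

    def sizes(self) -> np.ndarray:
        """Ellipse size lambda_1 * lambda_2 * ... (local volume change)."""
        return np.prod(self.lam, axis=1)

    def major_angles(self) -> np.ndarray:
        """Major-axis angle in radians in [0, pi), d = 2 only."""
        if self.d != 2:
            raise ValueError("major_angles is defined for d = 2")
        v = self.V[:, :, 0]
        return np.mod(np.arctan2(v[:, 1], v[:, 0]), np.pi)


def _eig_sorted(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched eigendecomposition, eigenvalues descending.

    Near-ties (relative gap < 1e-9) are ordered by the angle of the
    eigenvector to the +x axis, and eigenvector signs are fixed so the
    largest-magnitude component is positive; both make V stable across
    hyperparameter grids where ranks would otherwise switch arbitrarily.
    """
    w, v = np.linalg.eigh(H)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    # canonical signs
    n, d = w.shape
    amax = np.argmax(np.abs(v), axis=1)  # (n, d)
    signs = np.sign(v[np.arange(n)[:, None], amax, np.arange(d)[None, :]])
    signs[signs == 0] = 1.0
    v = v * signs[:, None, :]
    if d >= 2:
        scale = np.maximum(np.abs(w[:, 0]), 1e-300)
        tied = np.abs(w[:, 0] - w[:, 1]) <= 1e-9 * scale
        if np.any(tied):
            ang = np.mod(np.arctan2(v[:, 1, :], v[:, 0, :]), np.pi)  # (n, d)
            for i in np.nonzero(tied)[0]:
                order = np.argsort(ang[i], kind="stable")
                w[i] = w[i][order]
                v[i] = v[i][:, order]
    return w, v


def local_distortions(laplacian: LaplacianOperator, embedding: Embedding) -> LocalMetricField:
    """Estimate the distortion matrix H at every embedded point."""
    Y = embedding.Y
    n, d = Y.shape
    if laplacian.n != n:
        raise ValueError(
            f"embedding has {n} rows but Laplacian is {laplacian.n} x {laplacian.n}"
        )
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    C = laplacian.L.tocoo()
    diff = Y[C.col] - Y[C.row]  # (nnz, d)
    H = np.zeros((n, d, d))
    half = 0.5 * C.data
    for a in range(d):
        for b in range(a, d):
            acc = np.zeros(n)
            np.add.at(acc, C.row, half * diff[:, a] * diff[:, b])
            H[:, a, b] = acc
            if b != a:
                H[:, b, a] = acc
    lam, V = _eig_sorted(H)
    G = _pinv_field(lam, V)
    return LocalMetricField(H=H, lam=lam, V=V, G=G)


def _pinv_field(lam: np.ndarray, V: np.ndarray) -> np.ndarray:
    inv = np.where(lam > PINV_FLOOR, 1.0 / np.maximum(lam, PINV_FLOOR), 0.0)
    return np.einsum("nij,nj,nkj->nik", V, inv, V)


def truncate_singular_values(field: LocalMetricField, cap: float) -> LocalMetricField:
    """Clip eigenvalues at ``cap`` and rebuild H = V diag(lam) V^T."""
    if not np.isfinite(cap) or cap <= 0:
        raise ValueError(f"cap must be positive, got {cap!r}")
    affected = int(np.sum(np.any(field.lam > cap, axis=1)))
    lam = np.minimum(field.lam, cap)
    H = np.einsum("nij,nj,nkj->nik", field.V, lam, field.V)
    return replace(
        field, H=H, lam=lam, G=_pinv_field(lam, field.V),
        cap=float(cap), n_truncated=affected,
    )


def normalize_metrics(field: LocalMetricField) -> LocalMetricField:
    """Divide every H by the global factor s = (1/4n) sum_i sum_kl H_i[k, l].

    The sum runs over *all* d^2 matrix entries, signed off-diagonals
    included; after normalization, recomputing s on the output gives 1.
    """
    s = float(field.H.sum() / (4.0 * field.n))
    if s <= 0:
        raise RuntimeError(
            f"normalization factor s={s:g} is not positive; the signed "
            "off-diagonal sum dominates the trace on this field"
        )
    lam = field.lam / s
    return replace(
        field, H=field.H / s, lam=lam, G=_pinv_field(lam, field.V),
        scale_factor=field.scale_factor * s,
    )


def condition_numbers(field: LocalMetricField) -> np.ndarray:
    """Anisotropy lambda_1 / lambda_d per point (1 = isotropic)."""
    lo = field.lam[:, -1]
    if np.any(lo <= 0):
        warnings.warn("zero minimal eigenvalue; condition number reported as inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(lo > 0, field.lam[:, 0] / np.where(lo > 0, lo, 1.0), np.inf)
    return out


def metric_table(field: LocalMetricField, sample_ids=None) -> pd.DataFrame:
    """One row per sample: id, upper-triangle of H, eigenvalues, angle, scale."""
    n, d = field.n, field.d
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    rec = {"id": list(sample_ids)}
    for a in range(d):
        for b in range(a, d):
            rec[f"H{a + 1}{b + 1}"] = field.H[:, a, b]
    for j in range(d):
        rec[f"lambda{j + 1}"] = field.lam[:, j]
    if d == 2:
        rec["angle"] = field.major_angles()
    rec["scale_factor"] = np.full(n, field.scale_factor)
    return pd.DataFrame(rec)
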