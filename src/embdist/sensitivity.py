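"""Stability of the local metric field across its own hyperparameters.

The estimator has two knobs that a practitioner may mis-set: the graph
radius r (how far the kernel is truncated) and the rescaling bandwidth
entering the 4/eps^2 Laplacian scaling.  ``expand_geoms`` re-builds the
affinity/Laplacian geometry over a full-factorial grid of radius factors
and rescaling values; ``metric_sensitivity`` re-estimates the spectra per
cell and summarizes per-point relative eigenvalue ranges along each axis
of the grid, plus eigenvector stability across adjacent cells.

Per cell, the kernel width follows the default coupling eps_kernel =
radius / 3, while the grid's epsilon values play the rescaling role; the
two axes therefore probe truncation error and output scaling separately.
Cells whose radius graph comes out disconnected are recorded as failed
with a reason and excluded from the summaries rather than aborting the
grid.  Because (P - I) depends only on the radius (through graph and
kernel) and the rescaling enters as the scalar 4/eps^2, each radius's
Markov matrix is factored once and reused across the epsilon axis; the
per-cell results are identical to independent reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import Embedding, PointSet, build_radius_graph, gaussian_kernel
from .rmetric import LocalMetricField, geometric_laplacian, local_distortions

__all__ = [
    "SensitivityGrid",
    "SensitivityResult",
    "expand_geoms",
    "metric_sensitivity",
    "sensitivity_table",
]


@dataclass
class GridCell:
    radius: float
    epsilon: float
    kernel_epsilon: float
    laplacian: object = None   # LaplacianOperator when ok
    failed: str = None         # reason when failed

    @property
    def ok(self) -> bool:
        return self.failed is None


@dataclass
class SensitivityGrid:
    radius_factors: np.ndarray
    epsilon_values: np.ndarray
    base_radius: float
    cells: dict  # (fi, ei) -> GridCell

    def cell(self, fi: int, ei: int) -> GridCell:
        return self.cells[(fi, ei)]


@dataclass
class SensitivityResult:
    """Per-cell spectra and the stability summary.

    ``lam`` has shape (n_factors, n_eps, n, d) with NaN in failed cells;
    ``V`` matches with an extra trailing axis.  Relative ranges are
    (max - min) / |mean| per point and component along one grid axis,
    ignoring failed cells.
    """

    grid: SensitivityGrid
    lam: np.ndarray
    V: np.ndarray
    rel_range_eps: np.ndarray   # (n_factors, n, d)
    rel_range_radius: np.ndarray  # (n_eps, n, d)
    median_rel_range_eps: float
    median_rel_range_radius: float
    n_eigvec_swaps: int
    n_failed_cells: int


def expand_geoms(
    points: PointSet, base_radius: float, radius_factors, epsilon_values,
    kernel_epsilon: float = None,
) -> SensitivityGrid:
    """Build one affinity/Laplacian geometry per (radius factor, epsilon).

    ``kernel_epsilon`` overrides the default radius/3 coupling (it is then
    held fixed across the radius axis).
    """
    radius_factors = np.asarray(radius_factors, dtype=float)
    epsilon_values = np.asarray(epsilon_values, dtype=float)
    if np.any(radius_factors <= 0) or np.any(epsilon_values <= 0):
        raise ValueError("radius factors and epsilon values must be positive")
    if base_radius <= 0:
        raise ValueError("base_radius must be positive")
    cells = {}
    for fi, f in enumerate(radius_factors):
        r = float(base_radius * f)
        k_eps = float(kernel_epsilon) if kernel_epsilon is not None else r / 3.0
        fail = None
        lap_by_eps = {}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                graph = build_radius_graph(points, r)
        except Warning as wmsg:  # disconnected graph
            fail = f"disconnected radius graph at r={r:g}: {wmsg}"
        except ValueError as err:
            fail = str(err)
        if fail is None:
            kern = gaussian_kernel(graph, k_eps)
            for ei, eps in enumerate(epsilon_values):
                lap_by_eps[ei] = geometric_laplacian(kern, float(eps))
        for ei, eps in enumerate(epsilon_values):
            cells[(fi, ei)] = GridCell(
                radius=r, epsilon=float(eps), kernel_epsilon=k_eps,
                laplacian=lap_by_eps.get(ei), failed=fail,
            )
    return SensitivityGrid(
        radius_factors=radius_factors, epsilon_values=epsilon_values,
        base_radius=float(base_radius), cells=cells,
    )


def _nan_rel_range(lam: np.ndarray, axis: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        rng = np.nanmax(lam, axis=axis) - np.nanmin(lam, axis=axis)
        return rng / np.abs(np.nanmean(lam, axis=axis))


def metric_sensitivity(grid: SensitivityGrid, embedding: Embedding) -> SensitivityResult:
    """Estimate spectra per grid cell and summarize their stability."""
    nf, ne = len(grid.radius_factors), len(grid.epsilon_values)
    n, d = embedding.n, embedding.d
    lam = np.full((nf, ne, n, d), np.nan)
    V = np.full((nf, ne, n, d, d), np.nan)
    n_failed = 0
    for (fi, ei), cell in grid.cells.items():
        if not cell.ok:
            n_failed += 1
            continue
        fld: LocalMetricField = local_distortions(cell.laplacian, embedding)
        lam[fi, ei] = fld.lam
        V[fi, ei] = fld.V
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        rr_eps = _nan_rel_range(lam, axis=1)
        rr_rad = _nan_rel_range(lam, axis=0)
        med_eps = float(np.nanmedian(rr_eps))
        med_rad = float(np.nanmedian(rr_rad))
    swaps = _count_eigvec_swaps(lam, V)
    return SensitivityResult(
        grid=grid, lam=lam, V=V,
        rel_range_eps=rr_eps, rel_range_radius=rr_rad,
        median_rel_range_eps=med_eps, median_rel_range_radius=med_rad,
        n_eigvec_swaps=swaps, n_failed_cells=n_failed,
    )


def _count_eigvec_swaps(lam: np.ndarray, V: np.ndarray, tie_tol: float = 0.2) -> int:
    """Count eigenvector rank switches between cells adjacent in radius.

    Two adjacent cells are matched by maximal |cos angle| between
    eigenvectors; a crossed matching at nearly equal eigenvalues is a
    benign rank switch (counted, not treated as instability).
    """
    nf, ne = lam.shape[:2]
    swaps = 0
    for ei in range(ne):
        for fi in range(nf - 1):
            a, b = V[fi, ei], V[fi + 1, ei]
            if np.any(np.isnan(a)) or np.any(np.isnan(b)):
                continue
            # |cos| between each pair of leading eigenvectors, per point
            cos_keep = np.abs(np.einsum("nk,nk->n", a[:, :, 0], b[:, :, 0]))
            cos_cross = np.abs(np.einsum("nk,nk->n", a[:, :, 0], b[:, :, 1]))
            crossed = cos_cross > cos_keep
            la = lam[fi, ei]
            with np.errstate(invalid="ignore", divide="ignore"):
                near_tie = np.abs(la[:, 0] - la[:, 1]) <= tie_tol * np.abs(la[:, 0])
            swaps += int(np.sum(crossed & near_tie))
    return swaps


def sensitivity_table(result: SensitivityResult, sample_ids=None) -> pd.DataFrame:
    """Long-format table: id, radius_factor, epsilon, lambda_1..d, angle."""
    grid = result.grid
    nf, ne, n, d = result.lam.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    rows = []
    for fi in range(nf):
        for ei in range(ne):
            if not grid.cell(fi, ei).ok:
                continue
            rec = {
                "id": list(sample_ids),
                "radius_factor": np.full(n, grid.radius_factors[fi]),
                "epsilon": np.full(n, grid.epsilon_values[ei]),
            }
            for j in range(d):
                rec[f"lambda{j + 1}"] = result.lam[fi, ei, :, j]
            if d == 2:
                v = result.V[fi, ei, :, :, 0]
                rec["angle"] = np.mod(np.arctan2(v[:, 1], v[:, 0]), np.pi)
            rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)
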