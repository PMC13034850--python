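"""Model/Results front door tying the estimation stages together.

``DistortionModel`` holds a paired dataset (original coordinates X and an
embedding Y produced by any dimensionality-reduction method, treated as a
black box) together with the neighborhood-scale hyperparameters;
``fit()`` builds the graph, kernel and geometric Laplacian, estimates the
local metric field, and returns a ``DistortionResults`` carrying the
estimates plus accessors for every downstream diagnostic: fragmentation
screens, isometrized views, glyph geometry, sensitivity grids, and a
plain-text ``summary()``.

The default configuration mirrors the conventions used throughout:
a radius graph at r = 3 x the mean k-NN neighbor distance, Gaussian kernel
width r/3, and the rescaling bandwidth tied to the kernel width (which
makes the estimator consistent: an isometric embedding yields H = I).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fragmentation import (
    distance_pairs, fragmented_neighborhoods, kappa_sweep, screen,
)
from .graphs import (
    Embedding, PointSet, build_knn_graph, build_radius_graph, gaussian_kernel,
)
from .isometrize import global_isometrize, isometrize_at, neighborhood_links
from .rmetric import (
    condition_numbers, geometric_laplacian, local_distortions, metric_table,
    normalize_metrics, truncate_singular_values,
)
from .sensitivity import expand_geoms, metric_sensitivity
from .viz import boxplot_bins, ellipse_params, hair_params

__all__ = ["DistortionModel", "DistortionResults"]


class DistortionModel:
    """Distortion diagnostics for a paired (X, Y) dataset.

    Parameters
    ----------
    X : (n, D) array or PointSet
        Original (high-dimensional) coordinates.
    Y : (n, d) array or Embedding
        Paired embedding coordinates, d <= D.
    sample_ids, labels : optional
        Forwarded to :class:`PointSet` when X is a bare array.

    Examples
    --------
    >>> model = DistortionModel(X, Y)
    >>> res = model.fit()
    >>> res.condition_numbers().mean()
    """

    def __init__(self, X, Y, sample_ids=None, labels=None):
        self.points = X if isinstance(X, PointSet) else PointSet(
            X=X, sample_ids=sample_ids, labels=labels)
        self.embedding = Y if isinstance(Y, Embedding) else Embedding(Y=Y)
        if self.points.n != self.embedding.n:
            raise ValueError(
                f"X has {self.points.n} rows but Y has {self.embedding.n}")
        if self.embedding.d > self.points.dim:
            raise ValueError("embedding dimension exceeds data dimension")

    @classmethod
    def from_dataframes(cls, df_x: pd.DataFrame, df_y: pd.DataFrame,
                        label_col: str = None) -> "DistortionModel":
        """Build from indexed DataFrames (index = sample id)."""
        if not df_x.index.equals(df_y.index):
            raise ValueError("X and Y indexes do not match")
        labels = None
        if label_col is not None:
            labels = df_x[label_col].to_numpy()
            df_x = df_x.drop(columns=[label_col])
        return cls(df_x.to_numpy(float), df_y.to_numpy(float),
                   sample_ids=list(df_x.index), labels=labels)

    def fit(self, graph: str = "radius", k: int = 10, radius: float = None,
            kernel_epsilon: float = None, rescale_epsilon: float = None,
            cap: float = None, normalize: bool = False) -> "DistortionResults":
        """Estimate the local metric field H over all samples.

        Parameters
        ----------
        graph : {"radius", "knn"}
            Graph family; radius graphs give unbiased metric estimates and
            are the default.
        k : int
            Neighborhood size for knn graphs and for the default radius
            rule r = 3 x mean k-NN neighbor distance.
        radius, kernel_epsilon, rescale_epsilon : float, optional
            Explicit overrides; defaults are r as above, eps = r/3, and
            rescaling tied to the kernel width.
        cap : float, optional
            Eigenvalue truncation bound applied after estimation.
        normalize : bool
            Divide all H by the global mean-sum factor s.
        """
        if graph == "knn":
            g = build_knn_graph(self.points, k)
            if kernel_epsilon is None:
                kernel_epsilon = float(g.A.data.mean())
        elif graph == "radius":
            if radius is None:
                knn = build_knn_graph(self.points, k)
                radius = 3.0 * float(knn.A.data.mean())
            g = build_radius_graph(self.points, radius)
            if kernel_epsilon is None:
                kernel_epsilon = g.r / 3.0
        else:
            raise ValueError("graph must be 'radius' or 'knn'")
        kern = gaussian_kernel(g, kernel_epsilon)
        rescale = rescale_epsilon if rescale_epsilon is not None else kernel_epsilon
        lap = geometric_laplacian(kern, rescale)
        fld = local_distortions(lap, self.embedding)
        if cap is not None:
            fld = truncate_singular_values(fld, cap)
        if normalize:
            fld = normalize_metrics(fld)
        return DistortionResults(self, g, kern, lap, fld)


class DistortionResults:
    """Fitted local metric field plus diagnostic accessors."""

    def __init__(self, model, graph, kernel, laplacian, field):
        self.model = model
        self.points = model.points
        self.embedding = model.embedding
        self.graph = graph
        self.kernel = kernel
        self.laplacian = laplacian
        self.field = field
        self._pairs = None

    # -- estimates ---------------------------------------------------------
    @property
    def H(self):
        return self.field.H

    @property
    def lambdas(self):
        return self.field.lam

    def stretches(self):
        return self.field.stretches()

    def sizes(self):
        return self.field.sizes()

    def condition_numbers(self):
        return condition_numbers(self.field)

    def to_frame(self) -> pd.DataFrame:
        return metric_table(self.field, self.points.sample_ids)

    # -- fragmentation -----------------------------------------------------
    def pairs(self, directed: bool = False):
        if self._pairs is None or self._pairs.directed != directed:
            self._pairs = distance_pairs(
                self.points, self.embedding, self.graph, directed=directed)
        return self._pairs

    def outlier_flags(self, strategy: str = "bin", L: int = 10,
                      delta: int = 15, sigma: float = 3.0):
        return screen(self.pairs(), strategy=strategy, L=L, delta=delta,
                      sigma=sigma)

    def fragmentation(self, strategy: str = "bin", L: int = 10,
                      delta: int = 15, sigma: float = 3.0,
                      kappa: float = 0.1):
        flags = self.outlier_flags(strategy=strategy, L=L, delta=delta,
                                   sigma=sigma)
        return fragmented_neighborhoods(flags, self.graph, kappa)

    def kappa_sweep(self, kappas, strategy: str = "bin", L: int = 10,
                    delta: int = 15, sigma: float = 3.0):
        flags = self.outlier_flags(strategy=strategy, L=L, delta=delta,
                                   sigma=sigma)
        return kappa_sweep(flags, self.graph, kappas)

    # -- isometrization ----------------------------------------------------
    def isometrize_at(self, m, eps1=None, eps2=None, exponent=-0.5):
        return isometrize_at(self.embedding, self.field, m, eps1=eps1,
                             eps2=eps2, exponent=exponent)

    def global_isometrize(self, H_ref=None, exponent=-0.5):
        if H_ref is None:
            H_ref = self.field.H.mean(axis=0)
        return global_isometrize(self.embedding, H_ref, exponent=exponent)

    def links(self, fragmentation, m, delta, k=None):
        if k is None:
            k = self.graph.k or 10
        return neighborhood_links(fragmentation, self.graph, self.embedding,
                                  m, delta, k)

    # -- glyph geometry ----------------------------------------------------
    def ellipses(self, scale: float = 1.0, axis_scale: str = "sqrt_lambda"):
        return [
            ellipse_params(self.field.H[i], scale=scale,
                           axis_scale=axis_scale, center=self.embedding.Y[i])
            for i in range(self.field.n)
        ]

    def hairs(self):
        return [
            hair_params(self.field.H[i], center=self.embedding.Y[i])
            for i in range(self.field.n)
        ]

    def boxplot(self, L: int = 10, sigma: float = 3.0):
        return boxplot_bins(self.pairs(), L=L, sigma=sigma)

    # -- sensitivity -------------------------------------------------------
    def sensitivity(self, radius_factors=None, epsilon_values=None,
                    base_radius=None):
        if radius_factors is None:
            radius_factors = 2.0 ** np.arange(-1.0, 1.01, 0.2)
        if epsilon_values is None:
            epsilon_values = np.linspace(3.0, 7.0, 10)
        if base_radius is None:
            base_radius = (self.graph.r if self.graph.kind == "radius"
                           else 3.0 * float(self.graph.A.data.mean()))
        grid = expand_geoms(self.points, base_radius, radius_factors,
                            epsilon_values)
        return metric_sensitivity(grid, self.embedding)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Aggregate diagnostic report, statsmodels-style plain text."""
        fld = self.field
        lam = fld.lam
        cond = self.condition_numbers()
        finite = cond[np.isfinite(cond)]
        g = self.graph
        lines = [
            "Embedding distortion diagnostics",
            "=" * 48,
            f"samples                    {fld.n}",
            f"data dim / embedding dim   {self.points.dim} / {fld.d}",
            f"graph                      {g.kind}"
            + (f" (k={g.k})" if g.kind == "knn" else f" (r={g.r:.4g})"),
            f"edges                      {g.A.nnz // 2}",
            f"kernel epsilon             {self.kernel.epsilon:.4g}",
            f"rescale epsilon            {self.laplacian.rescale_epsilon:.4g}",
            "-" * 48,
            f"median lambda_1            {np.median(lam[:, 0]):.4g}",
            f"median lambda_{fld.d}            {np.median(lam[:, -1]):.4g}",
            f"median condition number    {np.median(finite):.4g}",
            f"mean ||H - I||_F           "
            f"{np.linalg.norm(fld.H - np.eye(fld.d), axis=(1, 2)).mean():.4g}",
        ]
        if fld.cap is not None:
            lines.append(f"eigenvalue cap             {fld.cap:g} "
                         f"({fld.n_truncated} samples truncated)")
        if fld.scale_factor != 1.0:
            lines.append(f"normalization factor s     {fld.scale_factor:.4g}")
        lines.append("=" * 48)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<DistortionResults n={self.field.n} d={self.field.d} "
                f"graph={self.graph.kind}>")
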