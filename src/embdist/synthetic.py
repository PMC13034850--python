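"""Synthetic generators and closed-form embedding maps with known truth.

Two generative models serve as the package's controlled test beds:

* a two-component planar Gaussian mixture with a 10:1 spread ratio, the
  canonical example of an embedding equalizing cluster variances that the
  local metrics should expose;
* a variable-density Swiss roll — a 2-D sheet rolled up in 3-D, with two
  Gaussian bumps of latent density at the ends of the roll on top of a
  uniform baseline, and optional isotropic observation noise.  Its latent
  coordinates are returned so that analytic reference embeddings (and
  planted defects with exactly known ground truth) can be constructed.

All randomness flows through ``numpy.random.default_rng(seed)``; the seed
is a required config field, so identical configs reproduce bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .graphs import Embedding, PointSet

__all__ = [
    "MixtureConfig",
    "SwissRollConfig",
    "simulate_gaussian_mixture",
    "simulate_swiss_roll",
    "analytic_embedding",
    "spiral_arclength",
]


@dataclass
class MixtureConfig:
    """Two-component isotropic Gaussian mixture in the plane.

    Defaults place component A at the origin with standard deviation 10 and
    component B at (30, 0) with standard deviation 1, 500 draws each.
    """

    seed: int
    n_per_component: int = 500
    mu_a: tuple = (0.0, 0.0)
    mu_b: tuple = (30.0, 0.0)
    tau_a: float = 10.0
    tau_b: float = 1.0

    def __post_init__(self):
        if self.n_per_component < 1:
            raise ValueError("n_per_component must be >= 1")
        if self.tau_a < 0 or self.tau_b < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass
class SwissRollConfig:
    """Variable-density Swiss roll in 3-D.

    The latent z mixes a uniform rectangle [0, a] x [0, b] (weight p) with
    two isotropic Gaussians at mu1, mu2 (weight (1-p)/2 each, sd nu).  The
    roll angle is t = 1.5 pi (z1 / a + 1) and the noiseless surface point is
    (t cos t, 10 z2 / b, t sin t); isotropic observation noise of sd tau is
    added on top.  Gaussian-component latents are not clamped to the
    rectangle by default (``clamp`` restricts them).
    """

    seed: int
    n: int = 1500
    p: float = 0.25
    a: float = 2.0
    b: float = 1.0
    mu1: tuple = None
    mu2: tuple = None
    nu: float = 0.2
    tau: float = 0.0
    clamp: bool = False

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("rectangle bounds a, b must be positive")
        if not (0 <= self.p <= 1):
            raise ValueError("mixture weight p must lie in [0, 1]")
        if self.nu < 0 or self.tau < 0:
            raise ValueError("nu and tau must be nonnegative")
        if self.mu1 is None:
            self.mu1 = (0.0, self.b / 2.0)
        if self.mu2 is None:
            self.mu2 = (self.a, self.b / 2.0)


def simulate_gaussian_mixture(config: MixtureConfig) -> PointSet:
    """Draw n points per component from N(mu_k, tau_k^2 I_2); labels A/B."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_component
    xa = rng.normal(loc=config.mu_a, scale=config.tau_a, size=(n, 2))
    xb = rng.normal(loc=config.mu_b, scale=config.tau_b, size=(n, 2))
    X = np.vstack([xa, xb])
    labels = np.array(["A"] * n + ["B"] * n)
    return PointSet(X=X, labels=labels)


def simulate_swiss_roll(config: SwissRollConfig):
    """Sample the variable-density Swiss roll.

    Returns
    -------
    points : PointSet
        3-D coordinates, labelled by latent mixture component
        ("uniform", "gauss1", "gauss2").
    z : (n, 2) array
        Latent sheet coordinates.
    t : (n,) array
        Roll angles 1.5 pi (z1 / a + 1), the natural 1-D ordering along
        the roll.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    w = [config.p, (1 - config.p) / 2.0, (1 - config.p) / 2.0]
    comp = rng.choice(3, size=n, p=w)
    z = np.empty((n, 2))
    uni = comp == 0
    z[uni] = rng.uniform([0.0, 0.0], [config.a, config.b], size=(int(uni.sum()), 2))
    for k, mu in ((1, config.mu1), (2, config.mu2)):
        mask = comp == k
        z[mask] = rng.normal(loc=mu, scale=config.nu, size=(int(mask.sum()), 2))
    if config.clamp:
        z[:, 0] = np.clip(z[:, 0], 0.0, config.a)
        z[:, 1] = np.clip(z[:, 1], 0.0, config.b)
    t = 1.5 * np.pi * (z[:, 0] / config.a + 1.0)
    mean = np.column_stack([t * np.cos(t), 10.0 * z[:, 1] / config.b, t * np.sin(t)])
    X = mean + rng.normal(scale=config.tau, size=mean.shape) if config.tau > 0 else mean
    labels = np.array(["uniform", "gauss1", "gauss2"])[comp]
    points = PointSet(X=X, labels=labels)
    return points, z, t


def spiral_arclength(t: np.ndarray) -> np.ndarray:
    """Arc length of the spiral (t cos t, t sin t) from 0: closed form."""
    t = np.asarray(t, dtype=float)
    return 0.5 * (t * np.sqrt(1.0 + t ** 2) + np.arcsinh(t))


def analytic_embedding(points: PointSet, map_kind: str, **params) -> Embedding:
    """Deterministic closed-form embeddings serving as ground-truth oracles.

    map_kind
        * ``identity`` — Y = X (requires D = target d).
        * ``rotation`` — global rotation by ``theta`` radians (2-D input).
        * ``diag_stretch`` — Y = X diag(scales).
        * ``cluster_scale`` — each labelled cluster scaled about its own
          centroid by ``scales[label]`` (unlisted labels keep scale 1).
        * ``unroll`` — Swiss-roll latents mapped to the isometric sheet
          chart (arc length along the roll, height); requires ``t``.
        * ``planted_break`` — the unroll chart with all points at
          ``t > t0`` translated by ``offset`` (default 10 x the 3-D data
          diameter) along both chart axes, planting fragmented
          neighborhoods whose ground truth is known by construction;
          requires ``t``, accepts ``t0`` (default mid-range).
    """
    X = points.X
    if map_kind == "identity":
        return Embedding(Y=X.copy())
    if map_kind == "rotation":
        theta = float(params["theta"])
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
        if X.shape[1] != 2:
            raise ValueError("rotation map requires 2-D input")
        return Embedding(Y=X @ R.T)
    if map_kind == "diag_stretch":
        scales = np.asarray(params["scales"], dtype=float)
        if scales.shape != (X.shape[1],):
            raise ValueError("scales must have one entry per input dimension")
        return Embedding(Y=X * scales)
    if map_kind == "cluster_scale":
        if points.labels is None:
            raise ValueError("cluster_scale requires labelled points")
        scales: dict = params["scales"]
        Y = X.astype(float).copy()
        for lab, s in scales.items():
            mask = points.labels == lab
            if not mask.any():
                raise ValueError(f"no points carry label {lab!r}")
            center = X[mask].mean(axis=0)
            Y[mask] = (X[mask] - center) * float(s) + center
        return Embedding(Y=Y)
    if map_kind in ("unroll", "planted_break"):
        t = np.asarray(params["t"], dtype=float)
        if t.shape != (X.shape[0],):
            raise ValueError("latent t must have one entry per point")
        Y = np.column_stack([spiral_arclength(t), X[:, 1]])
        if map_kind == "planted_break":
            t0 = float(params.get("t0", 0.5 * (t.min() + t.max())))
            offset = params.get("offset")
            if offset is None:
                offset = 10.0 * float(pdist(X).max())
            Y = Y.copy()
            Y[t > t0] += float(offset)
        return Embedding(Y=Y)
    raise ValueError(f"unknown map_kind {map_kind!r}")
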