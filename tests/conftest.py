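import numpy as np
import pytest

from embdist import (
    DistortionModel, Embedding, PointSet, SwissRollConfig,
    analytic_embedding, simulate_swiss_roll,
)


@pytest.fixture(scope="session")
def grid_points():
    """30 x 30 flat unit-spaced planar grid (isometry test bed)."""
    g = np.arange(30, dtype=float)
    X = np.array([(a, b) for a in g for b in g])
    return PointSet(X=X)


@pytest.fixture(scope="session")
def grid_fit(grid_points):
    """Fitted diagnostics for the identity embedding of the flat grid."""
    return DistortionModel(grid_points, Embedding(Y=grid_points.X.copy())).fit()


def grid_interior_mask(points, radius):
    """Points whose full radius-ball lies inside the grid domain."""
    X = points.X
    lo, hi = X.min(axis=0), X.max(axis=0)
    return np.all((X >= lo + radius) & (X <= hi - radius), axis=1)


@pytest.fixture(scope="session")
def swiss_roll():
    """Noiseless variable-density Swiss roll with latents, seed 7."""
    points, z, t = simulate_swiss_roll(SwissRollConfig(seed=7, tau=0.0))
    return points, z, t


@pytest.fixture(scope="session")
def unrolled(swiss_roll):
    points, _, t = swiss_roll
    return analytic_embedding(points, "unroll", t=t)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
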