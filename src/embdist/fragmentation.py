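"""Fragmented-neighborhood screening from paired distances.

A nonlinear embedding can tear a contiguous neighborhood apart: points that
are close in the original space land far from each other in the embedding
(or, less commonly, distant points collapse together).  The screen works on
the set D of (original distance, embedding distance) tuples over neighbor
edges.  Within strata of similar original distance — fixed-width bins, or a
running window of the Delta nearest pairs — an edge is *outlying* when its
embedding distance leaves the interval

    [median - sigma * IQR,  median + sigma * IQR]

(median-centered, deliberately distinct from Tukey's quartile-anchored
whisker rule used by the boxplot display).  A point is then the center of a
fragmented neighborhood when at least a fraction kappa of its neighbor
edges are outlying.

Pairs are deduplicated to unordered (i, j) records by default so that
symmetric edges do not double-weight the stratum statistics; the directed
variant is available for comparison with tools that count both directions.
Quantiles follow numpy's linear interpolation convention throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graphs import Embedding, NeighborGraph, PointSet

__all__ = [
    "DistancePairSet",
    "OutlierFlags",
    "FragmentationResult",
    "distance_pairs",
    "bin_outliers",
    "window_outliers",
    "screen",
    "fragmented_neighborhoods",
    "kappa_sweep",
    "pair_table",
    "point_table",
    "fragmentation_summary",
]


@dataclass
class DistancePairSet:
    """Neighbor-edge records (i, j, original distance, embedding distance)."""

    i: np.ndarray
    j: np.ndarray
    d_orig: np.ndarray
    d_embed: np.ndarray
    n_points: int
    directed: bool = False

    def __len__(self) -> int:
        return len(self.d_orig)


@dataclass
class OutlierFlags:
    """Per-pair outlier labels from one screening strategy.

    ``labels`` take values "inlier", "high" (embedding distance too large)
    or "low" (too small).  Bin mode also records the bin edges, per-bin
    median/IQR and a low-support mask for bins with fewer than 4 pairs,
    whose IQR is computed anyway but statistically fragile.
    """

    strategy: str  # {"bin", "window"}
    labels: np.ndarray  # (n_pairs,) of {inlier, high, low}
    pairs: "DistancePairSet"
    sigma: float
    L: int = None
    delta: int = None
    bin_index: np.ndarray = None
    bin_edges: np.ndarray = None
    bin_median: np.ndarray = None
    bin_iqr: np.ndarray = None
    low_support: np.ndarray = None

    @property
    def outlying(self) -> np.ndarray:
        return self.labels != "inlier"


@dataclass
class FragmentationResult:
    """Per-point outlying-neighbor fractions and center flags."""

    fraction: np.ndarray
    flagged: np.ndarray
    kappa: float
    neighbor_counts: np.ndarray

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def distance_pairs(
    points: PointSet, embedding: Embedding, graph: NeighborGraph,
    directed: bool = False,
) -> DistancePairSet:
    """Build the paired-distance set D over symmetrized neighbor edges.

    Self-pairs are excluded; embedding distances are recomputed from Y.
    """
    if not (points.n == embedding.n == graph.n):
        raise ValueError(
            f"inconsistent sizes: points n={points.n}, embedding n={embedding.n}, "
            f"graph n={graph.n}"
        )
    coo = sp.triu(graph.A, k=1).tocoo()
    i, j, d_orig = coo.row, coo.col, coo.data
    if directed:
        i, j = np.concatenate([i, j]), np.concatenate([j, i])
        d_orig = np.concatenate([d_orig, d_orig])
    d_embed = np.linalg.norm(embedding.Y[i] - embedding.Y[j], axis=1)
    return DistancePairSet(
        i=i.astype(int), j=j.astype(int), d_orig=np.asarray(d_orig, float),
        d_embed=d_embed, n_points=points.n, directed=directed,
    )


def _flag(d_embed: np.ndarray, med: float, iqr: float, sigma: float) -> np.ndarray:
    labels = np.full(len(d_embed), "inlier", dtype=object)
    labels[d_embed > med + sigma * iqr] = "high"
    labels[d_embed < med - sigma * iqr] = "low"
    return labels


def bin_outliers(pairs: DistancePairSet, L: int, sigma: float) -> OutlierFlags:
    """Bin-based screen: L fixed-width bins over the original distances.

    Binwidth is w = (d_max - d_min) / L with intervals
    [d_min + w (l-1), d_min + w l), the last interval closed above.  A bin
    whose embedding distances are all equal has IQR 0, so any pair off the
    bin median is flagged — a documented degenerate-case consequence.
    """
    if not isinstance(L, (int, np.integer)) or L < 1:
        raise ValueError(f"L must be a positive integer, got {L!r}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    d_orig, d_embed = pairs.d_orig, pairs.d_embed
    d_min, d_max = d_orig.min(), d_orig.max()
    if d_max == d_min:
        warnings.warn("all original distances identical; single-bin fallback")
        L = 1
        edges = np.array([d_min, d_min])
        bin_index = np.zeros(len(pairs), dtype=int)
    else:
        w = (d_max - d_min) / L
        edges = d_min + w * np.arange(L + 1)
        bin_index = np.minimum(((d_orig - d_min) // w).astype(int), L - 1)
    labels = np.full(len(pairs), "inlier", dtype=object)
    med = np.full(L, np.nan)
    iqr = np.full(L, np.nan)
    low_support = np.zeros(L, dtype=bool)
    for l in range(L):
        mask = bin_index == l
        if not mask.any():
            continue
        q1, q2, q3 = np.quantile(d_embed[mask], [0.25, 0.5, 0.75])
        med[l], iqr[l] = q2, q3 - q1
        low_support[l] = mask.sum() < 4
        labels[mask] = _flag(d_embed[mask], q2, q3 - q1, sigma)
    return OutlierFlags(
        strategy="bin", labels=labels, pairs=pairs, sigma=float(sigma), L=int(L),
        bin_index=bin_index, bin_edges=edges, bin_median=med, bin_iqr=iqr,
        low_support=low_support,
    )


def window_outliers(pairs: DistancePairSet, delta: int, sigma: float) -> OutlierFlags:
    """Window-based screen: per-pair running window of the Delta nearest pairs.

    For each record d0, the window collects the Delta pairs closest to it in
    original distance (|pi_O(d) - pi_O(d0)|, ties toward the lower record
    index, d0 itself included), and the median +/- sigma IQR rule is applied
    within the window.  Smoother than bins, but O(P Delta).
    """
    if not isinstance(delta, (int, np.integer)) or delta < 1:
        raise ValueError(f"delta must be a positive integer, got {delta!r}")
    if delta > len(pairs):
        raise ValueError(f"delta={delta} exceeds the number of pairs {len(pairs)}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    if delta < 4:
        warnings.warn(f"delta={delta} < 4 makes the window IQR unstable")
    d_orig, d_embed = pairs.d_orig, pairs.d_embed
    P = len(pairs)
    labels = np.full(P, "inlier", dtype=object)
    # sort once; each window is contiguous in the sorted order
    order = np.lexsort((np.arange(P), d_orig))
    ds = d_orig[order]
    for pos in range(P):
        lo = hi = pos  # window [lo, hi] inclusive, grown to delta members
        while hi - lo + 1 < delta:
            left_gap = ds[pos] - ds[lo - 1] if lo > 0 else np.inf
            right_gap = ds[hi + 1] - ds[pos] if hi < P - 1 else np.inf
            if left_gap < right_gap:
                lo -= 1
            elif right_gap < left_gap:
                hi += 1
            else:  # equal gaps: lower record index first
                if lo > 0 and (hi == P - 1 or order[lo - 1] < order[hi + 1]):
                    lo -= 1
                else:
                    hi += 1
        win = d_embed[order[lo: hi + 1]]
        q1, q2, q3 = np.quantile(win, [0.25, 0.5, 0.75])
        rec = order[pos]
        labels[rec] = _flag(d_embed[rec: rec + 1], q2, q3 - q1, sigma)[0]
    return OutlierFlags(
        strategy="window", labels=labels, pairs=pairs, sigma=float(sigma),
        delta=int(delta),
    )


def fragmented_neighborhoods(
    flags: OutlierFlags, graph: NeighborGraph, kappa: float,
) -> FragmentationResult:
    """Flag centers whose outlying-neighbor fraction reaches kappa.

    The denominator |N_i| counts stored neighbors (self excluded: a
    self-pair can never be outlying, so including it would only dilute the
    fraction).  Points without neighbors get fraction 0 with a warning.
    """
    if not (0 <= kappa <= 1):
        raise ValueError(f"kappa must lie in [0, 1], got {kappa!r}")
    n = graph.n
    deg = np.diff(graph.A.indptr)  # neighbors excluding self
    num = np.zeros(n)
    out = flags.outlying
    pairs = flags.pairs
    if pairs.n_points != n:
        raise ValueError("flags and graph cover different point universes")
    np.add.at(num, pairs.i[out], 1.0)
    if not pairs.directed:
        np.add.at(num, pairs.j[out], 1.0)
    if np.any(deg == 0):
        warnings.warn("points with empty neighborhoods get fraction 0")
    fraction = np.where(deg > 0, num / np.maximum(deg, 1), 0.0)
    flagged = fraction >= kappa
    flagged &= deg > 0
    if kappa == 0:
        flagged = deg > 0  # every point with at least one neighbor
    return FragmentationResult(
        fraction=fraction, flagged=flagged, kappa=float(kappa),
        neighbor_counts=deg,
    )


def screen(
    pairs: DistancePairSet, strategy: str = "bin", L: int = 10,
    delta: int = None, sigma: float = 3.0,
) -> OutlierFlags:
    """Dispatch to one of the two outlier strategies by name."""
    if strategy == "bin":
        return bin_outliers(pairs, L=L, sigma=sigma)
    if strategy == "window":
        return window_outliers(pairs, delta=delta, sigma=sigma)
    raise ValueError(f"unknown strategy {strategy!r}")


def kappa_sweep(flags: OutlierFlags, graph: NeighborGraph, kappas) -> pd.DataFrame:
    """Flagged-center counts along a kappa grid (weakly decreasing)."""
    kappas = np.asarray(kappas, dtype=float)
    if np.any((kappas < 0) | (kappas > 1)):
        raise ValueError("kappa values must lie in [0, 1]")
    counts = [
        fragmented_neighborhoods(flags, graph, kappa=k).n_flagged for k in kappas
    ]
    return pd.DataFrame({"kappa": kappas, "n_flagged": counts})


def pair_table(pairs: DistancePairSet, flags: OutlierFlags) -> pd.DataFrame:
    rec = {
        "i": pairs.i, "j": pairs.j,
        "d_orig": pairs.d_orig, "d_embed": pairs.d_embed,
        "label": flags.labels.astype(str),
    }
    if flags.bin_index is not None:
        rec["bin"] = flags.bin_index
    return pd.DataFrame(rec)


def point_table(result: FragmentationResult, sample_ids=None) -> pd.DataFrame:
    n = len(result.fraction)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame({
        "id": list(sample_ids),
        "fraction": result.fraction,
        "flagged": result.flagged,
    })


def fragmentation_summary(flags: OutlierFlags, result: FragmentationResult) -> str:
    """JSON summary of one screening run."""
    return json.dumps({
        "strategy": flags.strategy,
        "L": flags.L,
        "delta": flags.delta,
        "sigma": flags.sigma,
        "kappa": result.kappa,
        "n_flagged_pairs": int(flags.outlying.sum()),
        "n_flagged_centers": result.n_flagged,
    }, indent=2, sort_keys=True)
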