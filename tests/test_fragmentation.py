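import numpy as np
import pytest

from embdist import (
    DistancePairSet, Embedding, PointSet, bin_outliers, build_knn_graph,
    build_radius_graph, distance_pairs, fragmented_neighborhoods, kappa_sweep,
    screen, window_outliers,
)


def random_pairs(rng, n_pairs=200, n_points=60, outlier_frac=0.05):
    """Synthetic pair records with heavy-tailed embedding distances."""
    i = rng.integers(0, n_points - 1, size=n_pairs)
    j = (i + rng.integers(1, n_points - 1, size=n_pairs)) % n_points
    d_orig = rng.uniform(0.1, 10.0, size=n_pairs)
    d_embed = d_orig * rng.lognormal(0.0, 0.15, size=n_pairs)
    blow = rng.random(n_pairs) < outlier_frac
    d_embed[blow] *= 30.0
    return DistancePairSet(i=i, j=j, d_orig=d_orig, d_embed=d_embed,
                           n_points=n_points)


# ---------------------------------------------------------------- oracles
def oracle_bin_flags(d_orig, d_embed, L, sigma):
    """Independent quantile recomputation of the bin rule."""
    d_min, d_max = d_orig.min(), d_orig.max()
    w = (d_max - d_min) / L
    labels = np.full(len(d_orig), "inlier", dtype=object)
    for l in range(1, L + 1):
        lo = d_min + w * (l - 1)
        hi = d_min + w * l
        mask = ((d_orig >= lo) & (d_orig < hi)) if l < L else (
            (d_orig >= lo) & (d_orig <= hi))
        if not mask.any():
            continue
        vals = np.sort(d_embed[mask])
        med = np.quantile(vals, 0.5)
        iqr = np.quantile(vals, 0.75) - np.quantile(vals, 0.25)
        labels[mask & (d_embed > med + sigma * iqr)] = "high"
        labels[mask & (d_embed < med - sigma * iqr)] = "low"
    return labels


def oracle_window_flags(d_orig, d_embed, delta, sigma):
    """Per-record brute-force window construction."""
    P = len(d_orig)
    labels = np.full(P, "inlier", dtype=object)
    for p in range(P):
        gap = np.abs(d_orig - d_orig[p])
        win = np.lexsort((np.arange(P), gap))[:delta]
        med = np.quantile(d_embed[win], 0.5)
        iqr = (np.quantile(d_embed[win], 0.75)
               - np.quantile(d_embed[win], 0.25))
        if d_embed[p] > med + sigma * iqr:
            labels[p] = "high"
        elif d_embed[p] < med - sigma * iqr:
            labels[p] = "low"
    return labels


class TestDistancePairs:
    def test_identity_embedding_matches_distances(self, rng):
        X = rng.normal(size=(30, 2))
        pts = PointSet(X=X)
        g = build_knn_graph(pts, k=4)
        pairs = distance_pairs(pts, Embedding(Y=X.copy()), g)
        assert np.allclose(pairs.d_orig, pairs.d_embed)

    def test_single_edge_line(self):
        pts = PointSet(X=np.array([[0.0], [1.0], [3.0]]))
        with pytest.warns(UserWarning):
            g = build_radius_graph(pts, r=1.5)
        pairs = distance_pairs(pts, Embedding(Y=pts.X.copy()), g)
        assert len(pairs) == 1
        assert (pairs.i[0], pairs.j[0]) == (0, 1)

    def test_matches_bruteforce_enumeration(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 2))
        pts = PointSet(X=X)
        g = build_knn_graph(pts, k=4)
        pairs = distance_pairs(pts, Embedding(Y=Y), g)
        expected = set()
        for a in range(30):
            for b in g.neighbors(a):
                expected.add((min(a, b), max(a, b)))
        got = set(zip(pairs.i.tolist(), pairs.j.tolist()))
        assert got == expected
        # directed mode doubles the records
        directed = distance_pairs(pts, Embedding(Y=Y), g, directed=True)
        assert len(directed) == 2 * len(pairs)

    def test_shape_mismatch_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        pts = PointSet(X=X)
        g = build_knn_graph(pts, k=3)
        with pytest.raises(ValueError, match="inconsistent"):
            distance_pairs(pts, Embedding(Y=np.zeros((5, 2))), g)


class TestBinOutliers:
    def test_binwidth_formula(self):
        pairs = DistancePairSet(
            i=np.arange(5), j=np.arange(5) + 1,
            d_orig=np.array([0.0, 2.5, 4.0, 6.5, 8.0]),
            d_embed=np.ones(5), n_points=6)
        flags = bin_outliers(pairs, L=4, sigma=3.0)
        assert np.allclose(flags.bin_edges, [0, 2, 4, 6, 8])
        # I_2 = [2, 4): the record at 2.5 falls in bin index 1
        assert flags.bin_index[1] == 1
        # last interval closed above: d = 8.0 stays in bin 3
        assert flags.bin_index[4] == 3

    def test_degenerate_iqr_flags_off_median(self):
        pairs = DistancePairSet(
            i=np.arange(4), j=np.arange(4) + 1,
            d_orig=np.array([1.0, 1.1, 1.2, 1.3]),
            d_embed=np.array([2.0, 2.0, 2.0, 5.0]),
            n_points=5)
        flags = bin_outliers(pairs, L=1, sigma=3.0)
        assert flags.labels[3] == "high"
        assert np.all(flags.labels[:3] == "inlier")

    def test_matches_quantile_oracle(self, rng):
        pairs = random_pairs(rng)
        flags = bin_outliers(pairs, L=10, sigma=3.0)
        expected = oracle_bin_flags(pairs.d_orig, pairs.d_embed, 10, 3.0)
        assert np.array_equal(flags.labels, expected)

    def test_constant_orig_distance_fallback(self):
        pairs = DistancePairSet(
            i=np.arange(3), j=np.arange(3) + 1,
            d_orig=np.ones(3), d_embed=np.array([1.0, 1.0, 9.0]),
            n_points=4)
        with pytest.warns(UserWarning, match="single-bin"):
            flags = bin_outliers(pairs, L=5, sigma=1.0)
        assert flags.L == 1


class TestWindowOutliers:
    def test_homogeneous_pairs_unflagged(self, rng):
        d = rng.uniform(1, 5, size=50)
        pairs = DistancePairSet(i=np.zeros(50, int), j=np.ones(50, int),
                                d_orig=d, d_embed=d.copy(), n_points=2)
        flags = window_outliers(pairs, delta=10, sigma=1.0)
        assert np.all(flags.labels == "inlier")

    def test_invariant_to_record_order(self, rng):
        pairs = random_pairs(rng, n_pairs=100)
        flags = window_outliers(pairs, delta=15, sigma=2.0)
        perm = rng.permutation(100)
        # relabel records so the tie-break index ordering is preserved
        rank = np.empty(100, int)
        rank[np.argsort(perm, kind="stable")] = np.arange(100)
        shuffled = DistancePairSet(
            i=pairs.i[perm], j=pairs.j[perm], d_orig=pairs.d_orig[perm],
            d_embed=pairs.d_embed[perm], n_points=pairs.n_points)
        flags_shuffled = window_outliers(shuffled, delta=15, sigma=2.0)
        # compare as (i, j) -> label maps (set semantics)
        a = dict(zip(zip(pairs.i, pairs.j), flags.labels))
        b = dict(zip(zip(shuffled.i, shuffled.j), flags_shuffled.labels))
        assert a == b

    def test_matches_window_oracle(self, rng):
        pairs = random_pairs(rng, n_pairs=100)
        flags = window_outliers(pairs, delta=15, sigma=2.0)
        expected = oracle_window_flags(pairs.d_orig, pairs.d_embed, 15, 2.0)
        assert np.array_equal(flags.labels, expected)

    def test_small_delta_warns(self, rng):
        pairs = random_pairs(rng, n_pairs=20)
        with pytest.warns(UserWarning, match="unstable"):
            window_outliers(pairs, delta=3, sigma=2.0)


class TestFragmentedNeighborhoods:
    @pytest.fixture
    def setting(self, rng):
        X = rng.normal(size=(40, 3))
        Y = X[:, :2].copy()
        Y[::7] += 40.0  # displace a few points far away in the embedding
        pts = PointSet(X=X)
        g = build_knn_graph(pts, k=5)
        pairs = distance_pairs(pts, Embedding(Y=Y), g)
        flags = screen(pairs, strategy="bin", L=10, sigma=2.0)
        return g, flags

    def test_kappa_zero_flags_everything(self, setting):
        g, flags = setting
        res = fragmented_neighborhoods(flags, g, kappa=0.0)
        assert res.n_flagged == int((np.diff(g.A.indptr) > 0).sum())

    def test_no_outliers_no_centers(self, rng):
        X = rng.normal(size=(30, 2))
        pts = PointSet(X=X)
        g = build_knn_graph(pts, k=4)
        pairs = distance_pairs(pts, Embedding(Y=X.copy()), g)
        flags = screen(pairs, L=5, sigma=3.0)
        res = fragmented_neighborhoods(flags, g, kappa=0.1)
        assert res.n_flagged == 0

    def test_one_in_ten_at_kappa_point_one(self):
        # a point with exactly one outlying pair among ten neighbors is
        # flagged at the 10% threshold
        X = np.zeros((11, 2))
        X[:10, 0] = np.arange(10) * 0.1
        X[10] = (0.0, 0.1)
        pts = PointSet(X=X)
        g = build_radius_graph(pts, r=1.2)
        Y = X.copy()
        Y[10] = (50.0, 50.0)
        pairs = distance_pairs(pts, Embedding(Y=Y), g)
        flags = screen(pairs, L=1, sigma=2.0)
        res = fragmented_neighborhoods(flags, g, kappa=0.1)
        deg = res.neighbor_counts
        assert res.flagged[0]
        assert res.fraction[0] >= 0.1
        assert deg[0] == 10

    def test_fraction_matches_manual_count(self, setting):
        g, flags = setting
        res = fragmented_neighborhoods(flags, g, kappa=0.2)
        out = set()
        for rec, lab in enumerate(flags.labels):
            if lab != "inlier":
                out.add((flags.pairs.i[rec], flags.pairs.j[rec]))
        for i in range(g.n):
            nbrs = g.neighbors(i)
            cnt = sum((min(i, j), max(i, j)) in out for j in nbrs)
            assert res.fraction[i] == pytest.approx(cnt / max(len(nbrs), 1))
            assert res.flagged[i] == (len(nbrs) > 0
                                      and cnt / len(nbrs) >= 0.2)


class TestKappaSweep:
    def test_endpoints_and_monotonicity(self, rng):
        X = rng.normal(size=(50, 3))
        Y = X[:, :2].copy()
        Y[::5] += 30.0
        pts = PointSet(X=X)
        g = build_knn_graph(pts, k=5)
        pairs = distance_pairs(pts, Embedding(Y=Y), g)
        flags = screen(pairs, L=8, sigma=2.0)
        grid = np.linspace(0, 1, 11)
        sweep = kappa_sweep(flags, g, grid)
        assert sweep["n_flagged"].iloc[0] == g.n  # every point has neighbors
        assert np.all(np.diff(sweep["n_flagged"]) <= 0)
        # matches per-kappa independent recomputation
        for kap, cnt in zip(sweep["kappa"], sweep["n_flagged"]):
            assert cnt == fragmented_neighborhoods(flags, g, kap).n_flagged

    def test_sigma_monotonicity_of_pair_flags(self, rng):
        pairs = random_pairs(rng)
        n_out = [int(bin_outliers(pairs, L=10, sigma=s).outlying.sum())
                 for s in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(n_out) <= 0)
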