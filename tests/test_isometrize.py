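import numpy as np
import pytest

from embdist import (
    DistortionModel, Embedding, FragmentationResult, PointSet,
    build_knn_graph, export_corrected, global_isometrize, isometrize_at,
    local_average_metric, neighborhood_links,
)
from embdist.isometrize import linkset_json
from embdist.rmetric import LocalMetricField
from tests.conftest import grid_interior_mask


def constant_field(n, H0):
    H0 = np.asarray(H0, dtype=float)
    w, v = np.linalg.eigh(H0)
    lam = np.tile(w[::-1], (n, 1))
    V = np.tile(v[:, ::-1], (n, 1, 1))
    H = np.tile(H0, (n, 1, 1))
    G = np.tile(np.linalg.inv(H0), (n, 1, 1))
    return LocalMetricField(H=H, lam=lam, V=V, G=G)


class TestLocalAverageMetric:
    def test_convex_combination_of_constant_field(self, rng):
        Y = rng.normal(size=(20, 2))
        H0 = np.array([[3.0, 1.0], [1.0, 2.0]])
        fld = constant_field(20, H0)
        H_star, w = local_average_metric(fld, Embedding(Y=Y), m=(0.3, -1.0),
                                         eps2=0.5)
        assert np.allclose(H_star, H0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_kernel_concentration_limit(self, rng):
        Y = rng.normal(size=(15, 2))
        fld = constant_field(15, np.eye(2))
        fld.H[3] = np.diag([9.0, 4.0])
        H_star, _ = local_average_metric(fld, Embedding(Y=Y), m=Y[3],
                                         eps2=1e-3)
        assert np.allclose(H_star, np.diag([9.0, 4.0]), atol=1e-8)

    def test_underflow_falls_back_to_nearest(self, rng):
        Y = rng.normal(size=(10, 2))
        fld = constant_field(10, np.eye(2))
        fld.H[7] = np.diag([5.0, 5.0])
        far = Y[7] + np.array([1e4, 0.0])
        with pytest.warns(UserWarning, match="underflow"):
            H_star, w = local_average_metric(fld, Embedding(Y=Y), m=far,
                                            eps2=1e-2)
        assert w.sum() == pytest.approx(1.0)


class TestIsometrizeAt:
    def test_identity_metric_is_identity_map(self, rng):
        Y = rng.normal(size=(25, 2))
        fld = constant_field(25, np.eye(2))
        out, view = isometrize_at(Embedding(Y=Y), fld, m=(0.0, 0.0),
                                  eps1=1.0, eps2=1.0)
        assert np.allclose(out, Y)
        assert np.allclose(view.H_star, np.eye(2))

    def test_worked_inverse_example(self):
        # m = 0, H* = diag(4, 1), exponent -1, interpolation weight 1:
        # (2, 3) -> (0.5, 3)
        Y = np.array([[2.0, 3.0]])
        fld = constant_field(1, np.diag([4.0, 1.0]))
        out, _ = isometrize_at(Embedding(Y=Y), fld, m=(0.0, 0.0),
                               eps1=1e9, eps2=1.0, exponent=-1)
        assert np.allclose(out, [[0.5, 3.0]], atol=1e-9)

    def test_bandwidth_limits(self, rng):
        Y = rng.normal(size=(30, 2))
        fld = constant_field(30, np.diag([4.0, 0.25]))
        m = (0.1, 0.2)
        out_small, view = isometrize_at(Embedding(Y=Y), fld, m=m,
                                        eps1=1e-8, eps2=1.0)
        assert np.allclose(out_small, Y, atol=1e-8)
        out_big, view_big = isometrize_at(Embedding(Y=Y), fld, m=m,
                                          eps1=1e9, eps2=1.0)
        assert np.allclose(out_big, view_big.Y_tilde)

    def test_fixed_point_and_sandwich(self, rng):
        Y = rng.normal(size=(30, 2))
        Y[0] = (0.4, -0.2)
        fld = constant_field(30, np.diag([2.0, 0.5]))
        m = Y[0]
        out, view = isometrize_at(Embedding(Y=Y), fld, m=m, eps1=0.7,
                                  eps2=0.7)
        assert np.allclose(out[0], m, atol=1e-12)
        # every output lies on the segment between y and y_tilde
        seg = view.Y_tilde - Y
        t = np.einsum("nd,nd->n", out - Y, seg) / np.maximum(
            np.einsum("nd,nd->n", seg, seg), 1e-30)
        assert np.all((t >= -1e-12) & (t <= 1 + 1e-12))
        cross = (out - Y) - t[:, None] * seg
        assert np.abs(cross).max() < 1e-10

    def test_continuity_in_query_point(self, rng):
        Y = rng.normal(size=(40, 2))
        fld = constant_field(40, np.diag([3.0, 0.5]))
        m = np.array([0.25, -0.6])
        out0, _ = isometrize_at(Embedding(Y=Y), fld, m=m, eps1=1.0, eps2=1.0)
        h = 1e-6
        out1, _ = isometrize_at(Embedding(Y=Y), fld, m=m + (h, 0.0),
                                eps1=1.0, eps2=1.0)
        assert np.abs(out1 - out0).max() < 1e-3


class TestGlobalIsometrize:
    def test_identity(self, rng):
        Y = rng.normal(size=(10, 2))
        out = global_isometrize(Embedding(Y=Y), np.eye(2))
        assert np.allclose(out.Y, Y)

    def test_scalar_halving(self, rng):
        Y = rng.normal(size=(10, 2))
        out = global_isometrize(Embedding(Y=Y), np.diag([4.0, 4.0]),
                                exponent=-0.5)
        assert np.allclose(out.Y, Y / 2.0)

    def test_non_pd_rejected(self, rng):
        Y = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="positive-definite"):
            global_isometrize(Embedding(Y=Y), np.diag([1.0, -1.0]))

    def test_end_to_end_stretch_correction(self, grid_points):
        # fitting a diag(2,1)-stretched embedding, correcting with the
        # estimated H* at an interior point, then refitting must shrink
        # the distortion by at least half
        Y = grid_points.X @ np.diag([2.0, 1.0])
        res = DistortionModel(grid_points, Y).fit()
        interior = grid_interior_mask(grid_points, res.graph.r)
        before = np.median(np.linalg.norm(
            res.H[interior] - np.eye(2), axis=(1, 2)))
        m = Y[np.nonzero(interior)[0][len(interior) // 4]]
        H_star, _ = local_average_metric(res.field, res.model.embedding, m,
                                         eps2=3.0)
        corrected = global_isometrize(res.model.embedding, H_star,
                                      exponent=-0.5)
        res2 = DistortionModel(grid_points, corrected).fit()
        after = np.median(np.linalg.norm(
            res2.H[interior] - np.eye(2), axis=(1, 2)))
        assert after <= 0.5 * before


class TestNeighborhoodLinks:
    @pytest.fixture
    def setting(self, rng):
        X = rng.normal(size=(40, 3))
        pts = PointSet(X=X)
        g = build_knn_graph(pts, k=5)
        Y = rng.normal(size=(40, 2))
        flagged = np.zeros(40, bool)
        flagged[[3, 8, 20]] = True
        res = FragmentationResult(
            fraction=flagged.astype(float), flagged=flagged, kappa=0.5,
            neighbor_counts=np.diff(g.A.indptr))
        return pts, g, Embedding(Y=Y), res

    def test_no_flagged_centers_empty(self, setting):
        pts, g, emb, res = setting
        res.flagged[:] = False
        links = neighborhood_links(res, g, emb, m=(0, 0), delta=100.0, k=3)
        assert links.edges == []

    def test_delta_zero_on_center(self, setting):
        pts, g, emb, res = setting
        links = neighborhood_links(res, g, emb, m=emb.Y[8], delta=0.0, k=3)
        assert {a for a, _ in links.edges} == {8}
        assert len(links.edges) == 3

    def test_matches_bruteforce_filter(self, setting, rng):
        pts, g, emb, res = setting
        m = rng.normal(size=2)
        delta, k = 2.0, 4
        links = neighborhood_links(res, g, emb, m=m, delta=delta, k=k)
        expected = []
        for i in range(g.n):
            if not res.flagged[i]:
                continue
            if np.linalg.norm(emb.Y[i] - m) > delta:
                continue
            nbrs = g.neighbors(i)
            d = np.array([g.A[i, j] for j in nbrs])
            top = nbrs[np.lexsort((nbrs, d))[:k]]
            expected.extend((i, int(j)) for j in top)
        assert sorted(links.edges) == sorted(expected)

    def test_monotone_in_delta(self, setting):
        pts, g, emb, res = setting
        small = neighborhood_links(res, g, emb, m=(0, 0), delta=1.0, k=3)
        large = neighborhood_links(res, g, emb, m=(0, 0), delta=3.0, k=3)
        assert set(small.edges) <= set(large.edges)
        json_text = linkset_json(large)
        assert '"delta": 3.0' in json_text


class TestExportCorrected:
    def test_requires_frozen(self, rng):
        Y = rng.normal(size=(8, 2))
        fld = constant_field(8, np.eye(2))
        _, view = isometrize_at(Embedding(Y=Y), fld, m=(0, 0), eps1=1.0,
                                eps2=1.0)
        with pytest.raises(RuntimeError, match="frozen"):
            export_corrected(view, fld)

    def test_identity_view_roundtrip(self, rng, tmp_path):
        Y = rng.normal(size=(8, 2))
        fld = constant_field(8, np.eye(2))
        _, view = isometrize_at(Embedding(Y=Y), fld, m=(0, 0), eps1=1.0,
                                eps2=1.0)
        df = export_corrected(view.freeze(), fld)
        assert list(df.columns) == ["id", "x", "y", "angle", "size1", "size2"]
        assert len(df) == 8
        assert np.allclose(df[["x", "y"]].to_numpy(), Y)
        path = tmp_path / "corrected.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert np.allclose(back[["x", "y", "angle", "size1", "size2"]],
                           df[["x", "y", "angle", "size1", "size2"]])
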