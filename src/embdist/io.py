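"""Readers, writers, run configuration and the end-to-end pipeline.

Matrices come in as delimited text (CSV/TSV with a header row of feature
names and the sample id in the first column) or Matrix Market files with a
sidecar id list (one id per line).  All floating-point output is written
with 9 significant digits, and every artifact directory carries a JSON
manifest embedding the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .fragmentation import (
    distance_pairs, fragmented_neighborhoods, fragmentation_summary,
    pair_table, point_table, screen,
)
from .graphs import (
    Embedding, PointSet, build_knn_graph, build_radius_graph,
    gaussian_kernel, graph_to_edge_table, select_epsilon,
)
from .isometrize import export_corrected, isometrize_at
from .rmetric import (
    geometric_laplacian, local_distortions, metric_table,
    normalize_metrics, truncate_singular_values,
)
from .sensitivity import expand_geoms, metric_sensitivity, sensitivity_table
from .viz import ellipse_params, render_svg

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_matrix", "write_matrix", "run_pipeline"]

FLOAT_FORMAT = "%.9g"


def _detect_format(path: Path, fmt: str = None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix in (".mtx",):
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_matrix(path, format: str = None, ids_path=None, kind: str = "points"):
    """Read a sample-by-feature matrix as a PointSet or Embedding.

    CSV/TSV files need a header row and the sample id in the first column;
    MTX files are densified and need ``ids_path`` (one id per line).
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as err:
            raise ValueError(f"failed to parse {path}: {err}") from None
        bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
        if len(bad):
            raise ValueError(
                f"non-numeric cells in {path.name}, columns {list(bad)}"
            )
        X = df.to_numpy(dtype=float)
        ids = [str(s) for s in df.index]
    elif fmt == "mtx":
        X = scipy.io.mmread(path)
        if sp.issparse(X):
            X = np.asarray(X.todense(), dtype=float)
        if ids_path is None:
            ids = None
        else:
            ids = Path(ids_path).read_text().split()
            if len(ids) != X.shape[0]:
                raise ValueError(
                    f"id sidecar has {len(ids)} entries but matrix has "
                    f"{X.shape[0]} rows"
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if kind == "points":
        return PointSet(X=X, sample_ids=ids)
    if kind == "embedding":
        return Embedding(Y=X)
    raise ValueError(f"kind must be 'points' or 'embedding', got {kind!r}")


def write_matrix(obj, path, format: str = "csv"):
    """Write a PointSet/Embedding back to delimited text (9 sig. digits)."""
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    if isinstance(obj, PointSet):
        df = pd.DataFrame(
            obj.X, index=obj.sample_ids,
            columns=[f"f{j}" for j in range(obj.dim)],
        )
        df.index.name = "id"
    else:
        df = pd.DataFrame(
            obj.Y, index=[f"s{i}" for i in range(obj.n)],
            columns=[f"e{j}" for j in range(obj.Y.shape[1])],
        )
        df.index.name = "id"
    df.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)
    return path


@dataclass
class RunConfig:
    """Everything one diagnostic run needs, serializable into manifests."""

    x_path: str = None
    y_path: str = None
    labels_path: str = None
    out_dir: str = "embdist_out"
    seed: int = 0
    # graph
    graph_kind: str = "radius"      # {"knn", "radius"}
    k: int = 10
    radius: float = None            # default: 3 x mean k-NN neighbor distance
    kernel_epsilon: float = None    # default: radius / 3
    rescale_epsilon: float = None   # default: kernel_epsilon
    # post-processing
    cap: float = None
    normalize: bool = False
    # fragmentation
    strategy: str = "bin"
    L: int = 10
    delta: int = 15
    sigma: float = 3.0
    kappa: float = 0.1
    # isometrization
    m: tuple = None
    eps1: float = None
    eps2: float = None
    exponent: float = -0.5
    # sensitivity (optional stage)
    run_sensitivity: bool = False
    radius_factors: tuple = tuple(np.round(2.0 ** np.arange(-1.0, 1.01, 0.2), 6))
    epsilon_values: tuple = tuple(np.linspace(3.0, 7.0, 10))

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, val in out.items():
            if isinstance(val, tuple):
                out[key] = list(val)
        return out

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _save(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path.name


def run_pipeline(config: RunConfig, points: PointSet = None,
                 embedding: Embedding = None) -> dict:
    """Run graph -> metrics -> fragmentation (-> sensitivity) -> views.

    Inputs may be passed in memory or read from the configured paths.
    Returns the manifest dict (also written to ``out_dir/manifest.json``);
    on a stage failure, partial outputs are kept and the manifest records
    the failing stage before the exception propagates.
    """
    t_start = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "artifacts": {},
        "timings_s": {},
        "failed_stage": None,
    }
    stage = "load"
    try:
        if points is None:
            if config.x_path is None:
                raise ValueError("no points given and no x_path configured")
            points = read_matrix(config.x_path, kind="points")
        if embedding is None:
            if config.y_path is None:
                raise ValueError("no embedding given and no y_path configured")
            embedding = read_matrix(config.y_path, kind="embedding")
        if config.labels_path:
            labels = Path(config.labels_path).read_text().split()
            points.labels = np.asarray(labels)

        stage = "graph"
        t0 = time.perf_counter()
        if config.graph_kind == "knn":
            graph = build_knn_graph(points, config.k)
        else:
            radius = config.radius
            if radius is None:
                knn = build_knn_graph(points, config.k)
                radius = 3.0 * float(knn.A.data.mean())
            graph = build_radius_graph(points, radius)
        kernel_eps = config.kernel_epsilon
        if kernel_eps is None:
            if graph.kind == "radius":
                kernel_eps = graph.r / 3.0
            else:
                kernel_eps = select_epsilon(points, config.k)
        kernel = gaussian_kernel(graph, kernel_eps)
        manifest["edge_count"] = int(graph.A.nnz // 2)
        manifest["timings_s"]["graph"] = round(time.perf_counter() - t0, 4)
        logger.info("graph stage: m=%d edges in %.2fs", manifest["edge_count"],
                    manifest["timings_s"]["graph"])
        manifest["artifacts"]["edges"] = _save(
            graph_to_edge_table(graph, kernel), out / "edges.tsv")

        stage = "rmetric"
        t0 = time.perf_counter()
        rescale = config.rescale_epsilon or kernel_eps
        lap = geometric_laplacian(kernel, rescale)
        fld = local_distortions(lap, embedding)
        if config.cap is not None:
            fld = truncate_singular_values(fld, config.cap)
        if config.normalize:
            fld = normalize_metrics(fld)
        manifest["timings_s"]["rmetric"] = round(time.perf_counter() - t0, 4)
        manifest["artifacts"]["metrics"] = _save(
            metric_table(fld, points.sample_ids), out / "metrics.tsv")

        stage = "fragmentation"
        t0 = time.perf_counter()
        pairs = distance_pairs(points, embedding, graph)
        flags = screen(pairs, strategy=config.strategy, L=config.L,
                       delta=config.delta, sigma=config.sigma)
        frag = fragmented_neighborhoods(flags, graph, config.kappa)
        manifest["timings_s"]["fragmentation"] = round(time.perf_counter() - t0, 4)
        manifest["artifacts"]["pairs"] = _save(
            pair_table(pairs, flags), out / "pairs.tsv")
        manifest["artifacts"]["centers"] = _save(
            point_table(frag, points.sample_ids), out / "centers.tsv")
        (out / "fragmentation.json").write_text(
            fragmentation_summary(flags, frag))
        manifest["artifacts"]["fragmentation"] = "fragmentation.json"
        manifest["n_flagged_centers"] = frag.n_flagged

        if config.run_sensitivity:
            stage = "sensitivity"
            t0 = time.perf_counter()
            base_r = graph.r if graph.kind == "radius" else 3.0 * float(
                graph.A.data.mean())
            grid = expand_geoms(points, base_r, config.radius_factors,
                                config.epsilon_values)
            sens = metric_sensitivity(grid, embedding)
            manifest["timings_s"]["sensitivity"] = round(
                time.perf_counter() - t0, 4)
            manifest["artifacts"]["sensitivity"] = _save(
                sensitivity_table(sens, points.sample_ids),
                out / "sensitivity.tsv")

        stage = "views"
        t0 = time.perf_counter()
        if embedding.d == 2:
            glyphs = [
                ellipse_params(fld.H[i], center=embedding.Y[i])
                for i in range(fld.n)
            ]
            render_svg(glyphs, out / "ellipses.svg")
            manifest["artifacts"]["ellipses"] = "ellipses.svg"
            m = config.m if config.m is not None else embedding.Y.mean(axis=0)
            _, view = isometrize_at(embedding, fld, m, eps1=config.eps1,
                                    eps2=config.eps2,
                                    exponent=config.exponent)
            view.freeze()
            corrected = export_corrected(view, fld, points.sample_ids)
            corrected.to_csv(out / "corrected.csv", index=False,
                             float_format=FLOAT_FORMAT)
            manifest["artifacts"]["corrected"] = "corrected.csv"
        manifest["timings_s"]["views"] = round(time.perf_counter() - t0, 4)
    except Exception:
        manifest["failed_stage"] = stage
        manifest["timings_s"]["total"] = round(time.perf_counter() - t_start, 4)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["timings_s"]["total"] = round(time.perf_counter() - t_start, 4)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
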