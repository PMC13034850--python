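"""Glyph geometry, binned boxplot statistics and static SVG rendering.

The local metric at a point is drawn as a Tissot-style ellipse: semi-axes
along the eigenvectors of H, lengths sqrt(lambda) by default (the linear
stretch; the raw-lambda convention is available), so a circle marks a
locally isometric region.  The compact alternative is a "hair": a segment
along the ellipse's *minor* axis whose length encodes the condition number
lambda_1/lambda_2, designed to reduce overplotting at large n.

The boxplot panel bins neighbor pairs by original distance and computes
quartiles with whiskers capped at sigma x IQR beyond the quartiles — the
display convention, intentionally different from the median-centered rule
the fragmentation screen uses; both conventions coexist and a regression
test pins their difference on a shared fixture.

SVG output is generated as plain text with one element per glyph/edge in a
fixed order, so re-rendering identical inputs yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragmentation import DistancePairSet
from .isometrize import LinkSet

__all__ = [
    "GlyphSpec",
    "BoxplotPanel",
    "ellipse_params",
    "hair_params",
    "boxplot_bins",
    "brush_select",
    "render_svg",
]

#: hair length reported when lambda_2 underflows to zero
HAIR_LENGTH_CAP = 1e6


@dataclass
class GlyphSpec:
    """One ellipse or hair glyph in embedding coordinates."""

    center: tuple
    kind: str  # {"ellipse", "hair"}
    semi_axes: tuple = None  # (s1, s2) with s1 >= s2 > 0, ellipse only
    angle: float = 0.0       # radians CCW from +x, in [0, pi)
    length: float = None     # hair only: condition number


def _spectrum_2d(H: np.ndarray):
    H = np.asarray(H, dtype=float)
    if H.shape != (2, 2):
        raise ValueError("glyph geometry is defined for 2 x 2 matrices")
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("H must be symmetric")
    w, v = np.linalg.eigh(H)
    lam1, lam2 = w[1], w[0]
    major = v[:, 1]
    angle = float(np.mod(np.arctan2(major[1], major[0]), np.pi))
    return lam1, lam2, angle


def ellipse_params(H, scale: float = 1.0, axis_scale: str = "sqrt_lambda",
                   center=(0.0, 0.0)) -> GlyphSpec:
    """Ellipse semi-axes and orientation for one distortion matrix."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if axis_scale not in ("lambda", "sqrt_lambda"):
        raise ValueError("axis_scale must be 'lambda' or 'sqrt_lambda'")
    lam1, lam2, angle = _spectrum_2d(H)
    lam1, lam2 = max(lam1, 0.0), max(lam2, 0.0)
    if axis_scale == "sqrt_lambda":
        s1, s2 = np.sqrt(lam1), np.sqrt(lam2)
    else:
        s1, s2 = lam1, lam2
    return GlyphSpec(center=tuple(center), kind="ellipse",
                     semi_axes=(scale * s1, scale * s2), angle=angle)


def hair_params(H, center=(0.0, 0.0)) -> GlyphSpec:
    """Minor-axis segment whose length is the condition number."""
    import warnings

    lam1, lam2, angle = _spectrum_2d(H)
    if lam2 <= 0:
        warnings.warn("lambda_2 = 0; hair length capped")
        length = HAIR_LENGTH_CAP
    else:
        length = lam1 / lam2
    return GlyphSpec(center=tuple(center), kind="hair",
                     angle=float(np.mod(angle + np.pi / 2, np.pi)),
                     length=float(length))


@dataclass
class BoxplotPanel:
    """Per-bin quartile statistics with capped whiskers and outlier ids."""

    bin_edges: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    q3: np.ndarray
    whisker_lo: np.ndarray
    whisker_hi: np.ndarray
    outliers_high: list  # per bin: array of pair record indices
    outliers_low: list
    sigma: float
    bin_index: np.ndarray


def boxplot_bins(pairs: DistancePairSet, L: int, sigma: float) -> BoxplotPanel:
    """Quartiles per original-distance bin, whiskers at Q1/Q3 -/+ sigma IQR."""
    if not isinstance(L, (int, np.integer)) or L < 1:
        raise ValueError(f"L must be a positive integer, got {L!r}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d_orig, d_embed = pairs.d_orig, pairs.d_embed
    d_min, d_max = d_orig.min(), d_orig.max()
    if d_max == d_min:
        L = 1
        edges = np.array([d_min, d_min])
        bin_index = np.zeros(len(pairs), dtype=int)
    else:
        w = (d_max - d_min) / L
        edges = d_min + w * np.arange(L + 1)
        bin_index = np.minimum(((d_orig - d_min) // w).astype(int), L - 1)
    q1 = np.full(L, np.nan)
    q2 = np.full(L, np.nan)
    q3 = np.full(L, np.nan)
    wlo = np.full(L, np.nan)
    whi = np.full(L, np.nan)
    out_hi, out_lo = [], []
    for l in range(L):
        mask = bin_index == l
        if not mask.any():  # empty bin emitted with null statistics
            out_hi.append(np.array([], dtype=int))
            out_lo.append(np.array([], dtype=int))
            continue
        a, b, c = np.quantile(d_embed[mask], [0.25, 0.5, 0.75])
        iqr = c - a
        q1[l], q2[l], q3[l] = a, b, c
        wlo[l], whi[l] = a - sigma * iqr, c + sigma * iqr
        idx = np.nonzero(mask)[0]
        out_hi.append(idx[d_embed[idx] > whi[l]])
        out_lo.append(idx[d_embed[idx] < wlo[l]])
    return BoxplotPanel(
        bin_edges=edges, q1=q1, q2=q2, q3=q3, whisker_lo=wlo, whisker_hi=whi,
        outliers_high=out_hi, outliers_low=out_lo, sigma=float(sigma),
        bin_index=bin_index,
    )


def brush_select(panel: BoxplotPanel, bins, region: str = "both") -> np.ndarray:
    """Outlier pair indices within the brushed bins and region."""
    if region not in ("high", "low", "both"):
        raise ValueError("region must be 'high', 'low' or 'both'")
    L = len(panel.q1)
    sel = []
    for b in bins:
        if not (0 <= b < L):
            raise IndexError(f"bin index {b} out of range [0, {L})")
        if region in ("high", "both"):
            sel.append(panel.outliers_high[b])
        if region in ("low", "both"):
            sel.append(panel.outliers_low[b])
    if not sel:
        return np.array([], dtype=int)
    return np.unique(np.concatenate(sel)).astype(int)


_SVG_HEADER = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
    'width="{w:g}" height="{h:g}" viewBox="{x0:g} {y0:g} {w:g} {h:g}">\n'
)

_DEFAULT_STYLE = {
    "ellipse_fill": "none",
    "ellipse_stroke": "#1f77b4",
    "ellipse_stroke_width": "0.02",
    "hair_stroke": "#333333",
    "hair_stroke_width": "0.02",
    "hair_unit": "0.1",
    "link_stroke": "#d62728",
    "link_stroke_width": "0.02",
    "box_stroke": "#000000",
    "box_fill": "#cccccc",
}


def _fmt(x: float) -> str:
    return f"{x:.9g}"


def render_svg(layers, path, style: dict = None,
               embedding=None, viewbox=None) -> str:
    """Write layered glyphs/links/boxplots as a standalone SVG 1.1 file.

    ``layers`` is a list whose items are GlyphSpec, LinkSet or BoxplotPanel
    instances (LinkSet items need ``embedding`` for endpoint coordinates).
    Elements are emitted in input order, so identical inputs re-render to
    byte-identical files.  Returns the path written.
    """
    style = {**_DEFAULT_STYLE, **(style or {})}
    body = []
    xs, ys = [], []

    def track(x, y):
        xs.append(float(x))
        ys.append(float(y))

    for layer in layers:
        if isinstance(layer, GlyphSpec):
            cx, cy = layer.center
            track(cx, cy)
            if layer.kind == "ellipse":
                s1, s2 = layer.semi_axes
                deg = np.degrees(layer.angle)
                body.append(
                    f'<ellipse cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
                    f'rx="{_fmt(s1)}" ry="{_fmt(s2)}" '
                    f'transform="rotate({_fmt(deg)} {_fmt(cx)} {_fmt(cy)})" '
                    f'fill="{style["ellipse_fill"]}" '
                    f'stroke="{style["ellipse_stroke"]}" '
                    f'stroke-width="{style["ellipse_stroke_width"]}"/>'
                )
            elif layer.kind == "hair":
                half = 0.5 * layer.length * float(style["hair_unit"])
                dx, dy = half * np.cos(layer.angle), half * np.sin(layer.angle)
                body.append(
                    f'<line x1="{_fmt(cx - dx)}" y1="{_fmt(cy - dy)}" '
                    f'x2="{_fmt(cx + dx)}" y2="{_fmt(cy + dy)}" '
                    f'stroke="{style["hair_stroke"]}" '
                    f'stroke-width="{style["hair_stroke_width"]}"/>'
                )
            else:
                raise ValueError(f"unknown glyph kind {layer.kind!r}")
        elif isinstance(layer, LinkSet):
            if embedding is None:
                raise ValueError("LinkSet layers require the embedding")
            for a, b in layer.edges:
                x1, y1 = embedding.Y[a][:2]
                x2, y2 = embedding.Y[b][:2]
                track(x1, y1)
                track(x2, y2)
                body.append(
                    f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
                    f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
                    f'stroke="{style["link_stroke"]}" '
                    f'stroke-width="{style["link_stroke_width"]}"/>'
                )
        elif isinstance(layer, BoxplotPanel):
            L = len(layer.q1)
            for l in range(L):
                if np.isnan(layer.q1[l]):
                    continue
                x0, x1 = layer.bin_edges[l], layer.bin_edges[l + 1]
                track(x0, layer.whisker_lo[l])
                track(x1, layer.whisker_hi[l])
                body.append(
                    f'<rect x="{_fmt(x0)}" y="{_fmt(layer.q1[l])}" '
                    f'width="{_fmt(x1 - x0)}" '
                    f'height="{_fmt(layer.q3[l] - layer.q1[l])}" '
                    f'fill="{style["box_fill"]}" stroke="{style["box_stroke"]}" '
                    f'stroke-width="0.01"/>'
                )
                mid = 0.5 * (x0 + x1)
                body.append(
                    f'<line x1="{_fmt(x0)}" y1="{_fmt(layer.q2[l])}" '
                    f'x2="{_fmt(x1)}" y2="{_fmt(layer.q2[l])}" '
                    f'stroke="{style["box_stroke"]}" stroke-width="0.02"/>'
                )
                body.append(
                    f'<line x1="{_fmt(mid)}" y1="{_fmt(layer.whisker_lo[l])}" '
                    f'x2="{_fmt(mid)}" y2="{_fmt(layer.whisker_hi[l])}" '
                    f'stroke="{style["box_stroke"]}" stroke-width="0.01"/>'
                )
        else:
            raise TypeError(f"unsupported layer type {type(layer).__name__}")
    if viewbox is not None:
        x0, y0, w, h = viewbox
    elif xs:
        pad = 1.0
        x0, y0 = min(xs) - pad, min(ys) - pad
        w, h = max(xs) - x0 + pad, max(ys) - y0 + pad
    else:
        x0 = y0 = 0.0
        w = h = 1.0
    doc = _SVG_HEADER.format(x0=x0, y0=y0, w=w, h=h) + "\n".join(body)
    doc += ("\n" if body else "") + "</svg>\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)
    return str(path)
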