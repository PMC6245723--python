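"""Planar geometry primitives shared by every microcirculation metric.

All coordinates are μm.  Polylines are (n, 2) float arrays with n >= 2.
Clipping and grid-crossing counts are delegated to shapely's exact planar
predicates; the conventions on boundary points, tangencies and collinear
overlaps are fixed here so that every metric sees the same geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import GeometryCollection, LineString, MultiLineString, box

from .model import FieldOfView


def _as_polyline(points: Sequence | np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError(
            f"polyline needs >=2 (x, y) points, got shape {pts.shape}"
        )
    return pts


def polyline_length(points: Sequence | np.ndarray) -> float:
    """Total Euclidean length of a piecewise-linear curve, in μm."""
    pts = _as_polyline(points)
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def clip_polyline_to_rect(
    points: Sequence | np.ndarray,
    rect: FieldOfView | tuple[float, float, float, float],
) -> list[np.ndarray]:
    """Connected sub-polylines of ``points`` inside a rectangle.

    ``rect`` is either a :class:`FieldOfView` (rectangle anchored at the
    origin) or an explicit ``(x0, y0, x1, y1)`` tuple.  Points exactly on
    the rectangle boundary are inside.  A polyline entirely outside the
    rectangle clips to an empty list.
    """
    pts = _as_polyline(points)
    if isinstance(rect, FieldOfView):
        x0, y0, x1, y1 = 0.0, 0.0, rect.width_um, rect.height_um
    else:
        x0, y0, x1, y1 = rect
    inter = LineString(pts).intersection(box(x0, y0, x1, y1))
    return [np.asarray(g.coords, dtype=float) for g in _iter_linestrings(inter)]


def _iter_linestrings(geom) -> Iterable[LineString]:
    if geom.is_empty:
        return
    if isinstance(geom, LineString):
        yield geom
    elif isinstance(geom, (MultiLineString, GeometryCollection)):
        for g in geom.geoms:
            yield from _iter_linestrings(g)
    # Point/MultiPoint contacts carry zero length and are dropped.


@dataclass(frozen=True)
class GridSpec:
    """The 3+3 counting grid of the De Backer method.

    Three vertical and three horizontal lines span the field of view; the
    score divides vessel crossings by the total grid-line length.  The
    default placement puts the lines at 1/4, 2/4 and 3/4 of each dimension
    ("three equally spaced" including the implicit border gaps).
    """

    vertical_xs: tuple[float, float, float]
    horizontal_ys: tuple[float, float, float]
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not all(0 < x < self.width_um for x in self.vertical_xs):
            raise ValueError("vertical grid lines must lie strictly inside the FOV")
        if not all(0 < y < self.height_um for y in self.horizontal_ys):
            raise ValueError("horizontal grid lines must lie strictly inside the FOV")

    @classmethod
    def for_fov(cls, fov: FieldOfView) -> "GridSpec":
        w, h = fov.width_um, fov.height_um
        return cls(
            vertical_xs=(w / 4, w / 2, 3 * w / 4),
            horizontal_ys=(h / 4, h / 2, 3 * h / 4),
            width_um=w,
            height_um=h,
        )

    @property
    def total_line_length_um(self) -> float:
        return 3.0 * self.height_um + 3.0 * self.width_um

    def lines(self) -> list[LineString]:
        segs = [
            LineString([(x, 0.0), (x, self.height_um)]) for x in self.vertical_xs
        ]
        segs += [
            LineString([(0.0, y), (self.width_um, y)]) for y in self.horizontal_ys
        ]
        return segs


def count_grid_crossings(points: Sequence | np.ndarray, grid: GridSpec) -> int:
    """Number of distinct crossings between a polyline and the grid lines.

    Each connected component of the intersection with one grid line counts
    once: a vertex lying exactly on a line is a single crossing shared by
    its two incident segments, a tangency (touch without sign change)
    counts once, and a sub-segment collinear with a grid line counts once
    regardless of overlap length — the conventions a human rater applies.
    """
    pts = _as_polyline(points)
    path = LineString(pts)
    n = 0
    for line in grid.lines():
        inter = path.intersection(line)
        if inter.is_empty:
            continue
        n += len(inter.geoms) if hasattr(inter, "geoms") else 1
    return n


def partition_quadrants(
    fov: FieldOfView,
) -> tuple[tuple[float, float, float, float], ...]:
    """Split the FOV into four half-open quadrant rectangles.

    Order: top-left, top-right, bottom-left, bottom-right, where "top"
    is small y (image convention).  Returned as (x0, y0, x1, y1) tuples;
    they tile the FOV exactly.
    """
    w, h = fov.width_um, fov.height_um
    mx, my = w / 2.0, h / 2.0
    return (
        (0.0, 0.0, mx, my),
        (mx, 0.0, w, my),
        (0.0, my, mx, h),
        (mx, my, w, h),
    )


def quadrant_of_point(x: float, y: float, fov: FieldOfView) -> int:
    """Index (0..3, TL/TR/BL/BR) of the half-open quadrant containing (x, y)."""
    if not (0.0 <= x < fov.width_um and 0.0 <= y < fov.height_um):
        raise ValueError(f"point ({x}, {y}) outside the field of view")
    col = int(x >= fov.width_um / 2.0)
    row = int(y >= fov.height_um / 2.0)
    return row * 2 + col


__all__ = [
    "GridSpec",
    "polyline_length",
    "clip_polyline_to_rect",
    "count_grid_crossings",
    "partition_quadrants",
    "quadrant_of_point",
]
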