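"""Independent brute-force oracles used to cross-check the metric engine.

Nothing here imports the geometry or metrics implementations under test:
lengths come from parametric Liang–Barsky segment clipping (exact) and
from stratified dense sampling (approximate), grid crossings from
rasterizing the polyline at 0.1 μm and counting sign changes, and the
six metrics are recomputed from those primitives.
"""

from __future__ import annotations

import math

import numpy as np

SMALL_MAX_UM = 20.0


def seg_length(p0, p1) -> float:
    return math.hypot(p1[0] - p0[0], p1[1] - p0[1])


def liang_barsky_clip_length(p0, p1, rect) -> float:
    """Exact length of the part of segment p0->p1 inside rect (x0,y0,x1,y1)."""
    x0, y0, x1, y1 = rect
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, p0[0] - x0), (dx, x1 - p0[0]),
        (-dy, p0[1] - y0), (dy, y1 - p0[1]),
    ):
        if p == 0.0:
            if q < 0.0:
                return 0.0
        else:
            r = q / p
            if p < 0.0:
                if r > t1:
                    return 0.0
                t0 = max(t0, r)
            else:
                if r < t0:
                    return 0.0
                t1 = min(t1, r)
    if t1 < t0:
        return 0.0
    return (t1 - t0) * seg_length(p0, p1)


def exact_clipped_length(points: np.ndarray, rect) -> float:
    pts = np.asarray(points, dtype=float)
    return sum(
        liang_barsky_clip_length(pts[i], pts[i + 1], rect)
        for i in range(len(pts) - 1)
    )


def sampled_clipped_length(points: np.ndarray, rect, n_per_seg: int = 10_000) -> float:
    """Stratified dense-sampling estimate of in-rect length."""
    x0, y0, x1, y1 = rect
    pts = np.asarray(points, dtype=float)
    a, b = pts[:-1], pts[1:]
    lengths = np.hypot(*(b - a).T)
    t = (np.arange(n_per_seg) + 0.5) / n_per_seg
    # (segments, samples, 2)
    samples = a[:, None, :] + t[None, :, None] * (b - a)[:, None, :]
    inside = (
        (samples[..., 0] >= x0) & (samples[..., 0] <= x1)
        & (samples[..., 1] >= y0) & (samples[..., 1] <= y1)
    )
    return float(np.sum(lengths * inside.mean(axis=1)))


def raster_crossings(points: np.ndarray, fov_w: float, fov_h: float,
                     step_um: float = 0.1) -> int:
    """Crossings of the 3+3 grid counted by 0.1 μm rasterization.

    The polyline is resampled at ``step_um`` spacing; a crossing of a
    grid line is a sign change of the perpendicular coordinate whose
    midpoint lies within the grid segment's extent.
    """
    pts = np.asarray(points, dtype=float)
    # resample
    segs = np.diff(pts, axis=0)
    lengths = np.hypot(*segs.T)
    chunks = [pts[:1]]
    for i, L in enumerate(lengths):
        n = max(1, int(math.ceil(L / step_um)))
        t = np.arange(1, n + 1) / n
        chunks.append(pts[i] + t[:, None] * segs[i])
    dense = np.vstack(chunks)
    total = 0
    for gx in (fov_w / 4, fov_w / 2, 3 * fov_w / 4):
        s0 = dense[:-1, 0] - gx
        s1 = dense[1:, 0] - gx
        flips = np.nonzero(np.sign(s0) * np.sign(s1) < 0)[0]
        # resampled points lie exactly on the original segments, so linear
        # interpolation locates the crossing ordinate exactly
        t = s0[flips] / (s0[flips] - s1[flips])
        y = dense[flips, 1] + t * (dense[flips + 1, 1] - dense[flips, 1])
        total += int(np.sum((y >= 0) & (y <= fov_h)))
    for gy in (fov_h / 4, fov_h / 2, 3 * fov_h / 4):
        s0 = dense[:-1, 1] - gy
        s1 = dense[1:, 1] - gy
        flips = np.nonzero(np.sign(s0) * np.sign(s1) < 0)[0]
        t = s0[flips] / (s0[flips] - s1[flips])
        x = dense[flips, 0] + t * (dense[flips + 1, 0] - dense[flips, 0])
        total += int(np.sum((x >= 0) & (x <= fov_w)))
    return total


def oracle_metrics(clip) -> dict:
    """All six metrics recomputed from the exact clipping primitive."""
    w, h = clip.fov.width_um, clip.fov.height_um
    fov_rect = (0.0, 0.0, w, h)
    small = [v for v in clip.vessels if v.diameter_um < SMALL_MAX_UM]
    total = sum(exact_clipped_length(v.centerline, fov_rect) for v in small)
    perfused = sum(
        exact_clipped_length(v.centerline, fov_rect)
        for v in small if int(v.flow) >= 2
    )
    area_mm2 = w * h / 1e6
    tvd = (total / 1000.0) / area_mm2
    ppv = None if total == 0.0 else perfused / total
    pvd = (perfused / 1000.0) / area_mm2

    crossings = sum(raster_crossings(v.centerline, w, h) for v in small)
    de_backer = crossings / (3 * (w + h) / 1000.0)

    quads = [
        (0.0, 0.0, w / 2, h / 2), (w / 2, 0.0, w, h / 2),
        (0.0, h / 2, w / 2, h), (w / 2, h / 2, w, h),
    ]
    modes = []
    for rect in quads:
        by_score = {s: 0.0 for s in range(4)}
        for v in small:
            by_score[int(v.flow)] += exact_clipped_length(v.centerline, rect)
        if all(l == 0.0 for l in by_score.values()):
            modes.append(None)
        else:
            best = max(by_score.values())
            modes.append(min(s for s, l in by_score.items() if l == best))
    present = [m for m in modes if m is not None]
    mfi = float(np.mean(present)) if present else None
    if len(present) < 2:
        hi = None
    else:
        mean = float(np.mean(present))
        hi = 0.0 if mean == 0.0 else (max(present) - min(present)) / mean
    return {
        "tvd_mm_per_mm2": tvd,
        "pvd_mm_per_mm2": pvd,
        "ppv_fraction": ppv,
        "mfi": mfi,
        "heterogeneity_index": hi,
        "de_backer_n_per_mm": de_backer,
        "crossings": crossings,
        "total_small_length_um": total,
        "quadrant_modes": modes,
    }


def random_clip(rng: np.random.Generator, clip_index: int = 0):
    """A random clip exercising clipping: vessels may leave the FOV and
    span all three size classes."""
    from microflow.model import (
        Clip, FieldOfView, FlowScore, QualityFlags, VesselSegment,
    )

    w = float(rng.uniform(600, 1400))
    h = float(rng.uniform(500, 1100))
    fov = FieldOfView(w, h)
    vessels = []
    for i in range(int(rng.integers(1, 8))):
        n_pts = int(rng.integers(2, 9))
        pts = np.column_stack([
            rng.uniform(-0.25 * w, 1.25 * w, n_pts),
            rng.uniform(-0.25 * h, 1.25 * h, n_pts),
        ])
        # nudge apart any coincident consecutive points
        for k in range(1, n_pts):
            if np.all(pts[k] == pts[k - 1]):
                pts[k] += 0.5
        diameter = float(rng.choice([6.0, 12.0, 19.0, 25.0, 55.0],
                                    p=[0.3, 0.3, 0.2, 0.1, 0.1]))
        vessels.append(VesselSegment(
            vessel_id=f"r{i}", centerline=pts,
            diameter_um=diameter,
            flow=FlowScore(int(rng.integers(0, 4))),
        ))
    return Clip(
        clip_id=f"rand{clip_index}", subject_id="R", time_point_h=6,
        fov=fov, vessels=tuple(vessels), duration_s=5.0,
        quality=QualityFlags(),
    )
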