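"""The six consensus microcirculation scores and clip-level workflow.

Per clip this module computes:

* TVD  — total small-vessel centerline length in view / FOV area (mm/mm²)
* PPV  — perfused small-vessel length / total small-vessel length
* PVD  — PPV × TVD (equivalently, perfused length / area)
* MFI  — mean over image quadrants of the predominant (length-weighted
  mode) flow score
* heterogeneity index — (max − min) quadrant mode / mean quadrant mode
* De Backer score — grid-line crossings / total grid-line length (n/mm)

Only *small* vessels (lumen diameter < 20 μm, the capillary range) enter
any reported metric; medium (20–50 μm) and large (> 50 μm) vessels are
carried in the data model but excluded from scoring.  A vessel is
*perfused* when its flow score is ≥ 2 (moderate or brisk).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np

from . import geometry
from .model import Clip, FlowScore, MetricSet

SMALL_VESSEL_MAX_DIAMETER_UM = 20.0
MEDIUM_VESSEL_MAX_DIAMETER_UM = 50.0

MIN_CLIP_DURATION_S = 3.0
MAX_CLIP_DURATION_S = 10.0


class SizeClass(str, Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


def classify_vessel_size(diameter_um: float) -> SizeClass:
    """Size class from lumen diameter: <20 μm small, 20–50 μm (inclusive)
    medium, >50 μm large."""
    if not diameter_um > 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    if diameter_um < SMALL_VESSEL_MAX_DIAMETER_UM:
        return SizeClass.SMALL
    if diameter_um <= MEDIUM_VESSEL_MAX_DIAMETER_UM:
        return SizeClass.MEDIUM
    return SizeClass.LARGE


def is_perfused(flow: FlowScore | int) -> bool:
    """Perfused means moderate or brisk flow (score >= 2)."""
    return FlowScore(int(flow)) >= FlowScore.MODERATE


def _small_vessels(clip: Clip):
    return [
        v for v in clip.vessels
        if classify_vessel_size(v.diameter_um) is SizeClass.SMALL
    ]


def _in_view_length_um(vessel, clip: Clip) -> float:
    pieces = geometry.clip_polyline_to_rect(vessel.centerline, clip.fov)
    return sum(geometry.polyline_length(p) for p in pieces)


def compute_tvd(clip: Clip) -> float:
    """Total vascular density: in-view small-vessel length / FOV area, mm/mm²."""
    total_um = sum(_in_view_length_um(v, clip) for v in _small_vessels(clip))
    return (total_um / 1000.0) / clip.fov.area_mm2


def compute_ppv(clip: Clip) -> Optional[float]:
    """Proportion of perfused vessels; ``None`` when no small vessel is in view."""
    total = 0.0
    perfused = 0.0
    for v in _small_vessels(clip):
        length = _in_view_length_um(v, clip)
        total += length
        if is_perfused(v.flow):
            perfused += length
    if total == 0.0:
        return None
    return perfused / total


def compute_pvd(clip: Clip) -> float:
    """Perfused vascular density = PPV × TVD (0 when no small vessels)."""
    ppv = compute_ppv(clip)
    if ppv is None:
        return 0.0
    return ppv * compute_tvd(clip)


def compute_de_backer(clip: Clip, small_only: bool = True) -> float:
    """De Backer score: vessel crossings of a 3+3 grid per mm of grid line.

    By default only small vessels are counted, consistent with all other
    reported metrics; set ``small_only=False`` to count every traced
    vessel.
    """
    grid = geometry.GridSpec.for_fov(clip.fov)
    vessels = _small_vessels(clip) if small_only else list(clip.vessels)
    crossings = sum(
        geometry.count_grid_crossings(v.centerline, grid) for v in vessels
    )
    return crossings / (grid.total_line_length_um / 1000.0)


@dataclass(frozen=True)
class QuadrantFlowSummary:
    """Length-by-flow-score breakdown of one image quadrant.

    ``mode_score`` is the flow score carrying the greatest clipped
    small-vessel centerline length in the quadrant; ties break toward the
    lower score (conservative: under-calls perfusion).  ``None`` when the
    quadrant contains no small-vessel length.
    """

    quadrant_index: int
    length_by_score: dict[FlowScore, float]
    mode_score: Optional[FlowScore]


TieBreak = Literal["lower", "higher"]


def summarize_quadrants(
    clip: Clip, tie_break: TieBreak = "lower"
) -> tuple[QuadrantFlowSummary, ...]:
    """Per-quadrant totals of clipped small-vessel length by flow score."""
    quads = geometry.partition_quadrants(clip.fov)
    lengths = [
        {score: 0.0 for score in FlowScore} for _ in quads
    ]
    for v in _small_vessels(clip):
        for qi, rect in enumerate(quads):
            pieces = geometry.clip_polyline_to_rect(v.centerline, rect)
            total = sum(geometry.polyline_length(p) for p in pieces)
            if total > 0.0:
                lengths[qi][v.flow] += total
    out = []
    for qi, by_score in enumerate(lengths):
        if all(l == 0.0 for l in by_score.values()):
            mode = None
        else:
            best = max(by_score.values())
            candidates = [s for s, l in by_score.items() if l == best]
            mode = min(candidates) if tie_break == "lower" else max(candidates)
        out.append(
            QuadrantFlowSummary(
                quadrant_index=qi, length_by_score=by_score, mode_score=mode
            )
        )
    return tuple(out)


EmptyQuadrant = Literal["skip", "zero"]


def _quadrant_modes(
    clip: Clip, tie_break: TieBreak, empty_quadrant: EmptyQuadrant
) -> list[Optional[int]]:
    modes: list[Optional[int]] = []
    for q in summarize_quadrants(clip, tie_break=tie_break):
        if q.mode_score is None:
            modes.append(0 if empty_quadrant == "zero" else None)
        else:
            modes.append(int(q.mode_score))
    return modes


def compute_mfi(
    clip: Clip,
    tie_break: TieBreak = "lower",
    empty_quadrant: EmptyQuadrant = "skip",
) -> Optional[float]:
    """Microcirculatory flow index: mean of the quadrant mode flow scores.

    Quadrants without any visible small vessel are skipped by default
    (absence of visible vessels is not absent flow); with
    ``empty_quadrant="zero"`` they contribute a score of 0.  ``None`` when
    every quadrant is empty.
    """
    modes = [m for m in _quadrant_modes(clip, tie_break, empty_quadrant)
             if m is not None]
    if not modes:
        return None
    return float(np.mean(modes))


def compute_heterogeneity(
    clip: Clip,
    tie_break: TieBreak = "lower",
    empty_quadrant: EmptyQuadrant = "skip",
) -> Optional[float]:
    """Flow heterogeneity index: (max − min) / mean of the quadrant modes.

    0 by convention when the mean mode is 0 (all-absent flow is perfectly
    homogeneous); ``None`` when fewer than two quadrants have a mode.
    """
    modes = [m for m in _quadrant_modes(clip, tie_break, empty_quadrant)
             if m is not None]
    if len(modes) < 2:
        return None
    mean = float(np.mean(modes))
    if mean == 0.0:
        return 0.0
    return (max(modes) - min(modes)) / mean


def score_clip(
    clip: Clip,
    tie_break: TieBreak = "lower",
    empty_quadrant: EmptyQuadrant = "skip",
    de_backer_small_only: bool = True,
) -> MetricSet:
    """All six metrics for one clip."""
    tvd = compute_tvd(clip)
    ppv = compute_ppv(clip)
    return MetricSet(
        tvd_mm_per_mm2=tvd,
        pvd_mm_per_mm2=0.0 if ppv is None else ppv * tvd,
        ppv_fraction=ppv,
        mfi=compute_mfi(clip, tie_break, empty_quadrant),
        heterogeneity_index=compute_heterogeneity(clip, tie_break, empty_quadrant),
        de_backer_n_per_mm=compute_de_backer(clip, small_only=de_backer_small_only),
    )


def rank_and_select_clips(clips: Sequence[Clip], max_n: int = 3) -> list[Clip]:
    """Quality-gate and rank one subject-time-point's clips; keep the best.

    Clips with a pressure or content artifact, or a duration outside the
    stabilized-sequence window of 3–10 s, are excluded.  Survivors are
    ranked by ordinal quality (count of clean flags, higher better), ties
    by longer duration, then lexicographic clip id; at most ``max_n``
    (default 3) are returned.
    """
    if clips:
        subjects = {(c.subject_id, c.time_point_h) for c in clips}
        if len(subjects) > 1:
            raise ValueError(
                f"clips span multiple subject/time points: {sorted(subjects)}"
            )
    eligible = [
        c for c in clips
        if not c.quality.pressure_artifact
        and not c.quality.content_artifact
        and MIN_CLIP_DURATION_S <= c.duration_s <= MAX_CLIP_DURATION_S
    ]
    eligible.sort(
        key=lambda c: (-c.quality.ordinal_quality, -c.duration_s, c.clip_id)
    )
    return eligible[:max_n]


def aggregate_time_point(selected: Sequence[Clip | MetricSet]) -> MetricSet:
    """Subject-time-point metrics: per-metric mean over clips, skipping missing.

    A metric is missing in the aggregate only when missing in every clip.
    The PVD = PPV × TVD identity is deliberately *not* re-imposed after
    averaging (means of ratios are not ratios of means); ``pvd <= tvd``
    still holds because it holds clipwise.
    """
    if not selected:
        raise ValueError("cannot aggregate an empty clip list")
    sets = [
        s if isinstance(s, MetricSet) else score_clip(s) for s in selected
    ]
    values: dict[str, Optional[float]] = {}
    for name in MetricSet.field_names():
        present = [getattr(s, name) for s in sets if getattr(s, name) is not None]
        values[name] = float(np.mean(present)) if present else None
    # densities are never None clipwise, so the aggregate is well-defined
    return MetricSet(**values)


__all__ = [
    "SizeClass",
    "QuadrantFlowSummary",
    "classify_vessel_size",
    "is_perfused",
    "compute_tvd",
    "compute_ppv",
    "compute_pvd",
    "compute_de_backer",
    "summarize_quadrants",
    "compute_mfi",
    "compute_heterogeneity",
    "score_clip",
    "rank_and_select_clips",
    "aggregate_time_point",
    "SMALL_VESSEL_MAX_DIAMETER_UM",
    "MEDIUM_VESSEL_MAX_DIAMETER_UM",
]
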