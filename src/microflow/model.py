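"""Domain types for sublingual microcirculation video analysis.

The unit of measurement is a *clip*: one stabilized sidestream dark field
video sequence, represented here by its manually traced vessel centerlines.
Each traced vessel carries a lumen diameter (μm) and a semiquantitative
flow score.  Coordinates are continuous 2-D, origin at the top-left of the
field of view, x rightward, y downward, in μm; the field of view is the
half-open rectangle [0, W) × [0, H).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

TIME_POINTS_H = (6, 24, 72)

ARMS = ("EGDT", "protocolized_noninvasive", "usual_care")


class FlowScore(IntEnum):
    """Semiquantitative per-vessel flow velocity class.

    0 = absent flow, 1 = noncontinuous/sluggish flow, 2 = moderate flow,
    3 = normal continuous/brisk flow.  A vessel is *perfused* when its
    score is >= 2.
    """

    ABSENT = 0
    SLUGGISH = 1
    MODERATE = 2
    BRISK = 3


@dataclass(frozen=True)
class FieldOfView:
    """Rectangular imaging field, [0, width) x [0, height), in μm."""

    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValueError(
                f"FieldOfView dimensions must be positive, got "
                f"{self.width_um} x {self.height_um}"
            )

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


@dataclass(frozen=True)
class VesselSegment:
    """One manually traced vessel: centerline polyline, lumen diameter, flow.

    The centerline is an ordered (n, 2) float array of (x, y) points in μm
    with at least two points and no repeated consecutive point.  The flow
    score applies to the whole traced vessel.
    """

    vessel_id: str
    centerline: np.ndarray
    diameter_um: float
    flow: FlowScore

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError(
                f"vessel {self.vessel_id!r}: centerline needs >=2 (x, y) "
                f"points, got array of shape {pts.shape}"
            )
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError(
                f"vessel {self.vessel_id!r}: consecutive centerline points "
                "must be distinct"
            )
        if not self.diameter_um > 0:
            raise ValueError(
                f"vessel {self.vessel_id!r}: diameter must be positive, got "
                f"{self.diameter_um}"
            )
        object.__setattr__(self, "centerline", pts)
        object.__setattr__(self, "flow", FlowScore(int(self.flow)))


N_QUALITY_FLAGS = 5


@dataclass(frozen=True)
class QualityFlags:
    """Per-clip acquisition-quality annotations.

    ``ordinal_quality`` is derived: the count of flags that are *not* set
    (0 worst, 5 best).  Clips with pressure or content artifacts are
    excluded from selection outright regardless of the ordinal score.
    """

    pressure_artifact: bool = False
    content_artifact: bool = False
    out_of_focus: bool = False
    bad_brightness: bool = False
    unstable: bool = False

    @property
    def ordinal_quality(self) -> int:
        flags = (
            self.pressure_artifact,
            self.content_artifact,
            self.out_of_focus,
            self.bad_brightness,
            self.unstable,
        )
        return sum(1 for f in flags if not f)


@dataclass(frozen=True)
class Clip:
    """All traces of one video clip plus acquisition metadata."""

    clip_id: str
    subject_id: str
    time_point_h: int
    fov: FieldOfView
    vessels: tuple[VesselSegment, ...] = ()
    duration_s: float = 0.0
    quality: QualityFlags = field(default_factory=QualityFlags)

    def __post_init__(self) -> None:
        if self.time_point_h not in TIME_POINTS_H:
            raise ValueError(
                f"clip {self.clip_id!r}: time_point_h must be one of "
                f"{TIME_POINTS_H}, got {self.time_point_h}"
            )
        if self.duration_s < 0:
            raise ValueError(
                f"clip {self.clip_id!r}: duration_s must be >= 0"
            )
        object.__setattr__(self, "vessels", tuple(self.vessels))


_METRIC_FIELDS = (
    "tvd_mm_per_mm2",
    "pvd_mm_per_mm2",
    "ppv_fraction",
    "mfi",
    "heterogeneity_index",
    "de_backer_n_per_mm",
)


@dataclass(frozen=True)
class MetricSet:
    """The six consensus microcirculation scores for one observation.

    ``None`` marks a genuinely missing value (e.g. PPV when no small
    vessel is visible); it is distinct from 0.  At the clip level
    PVD = PPV × TVD exactly; after averaging clips the identity is not
    re-imposed (means of ratios are not ratios of means), so only the
    weaker ``pvd <= tvd`` invariant is enforced here.
    """

    tvd_mm_per_mm2: float
    pvd_mm_per_mm2: float
    ppv_fraction: Optional[float]
    mfi: Optional[float]
    heterogeneity_index: Optional[float]
    de_backer_n_per_mm: float

    def __post_init__(self) -> None:
        if self.tvd_mm_per_mm2 < 0 or self.pvd_mm_per_mm2 < 0:
            raise ValueError("densities must be >= 0")
        if self.pvd_mm_per_mm2 > self.tvd_mm_per_mm2 * (1 + 1e-9) + 1e-12:
            raise ValueError(
                f"PVD ({self.pvd_mm_per_mm2}) cannot exceed TVD "
                f"({self.tvd_mm_per_mm2})"
            )
        if self.ppv_fraction is not None and not (
            -1e-12 <= self.ppv_fraction <= 1 + 1e-12
        ):
            raise ValueError(f"PPV must lie in [0, 1], got {self.ppv_fraction}")
        if self.mfi is not None and not (-1e-12 <= self.mfi <= 3 + 1e-12):
            raise ValueError(f"MFI must lie in [0, 3], got {self.mfi}")
        if self.heterogeneity_index is not None and self.heterogeneity_index < 0:
            raise ValueError("heterogeneity index must be >= 0")
        if self.de_backer_n_per_mm < 0:
            raise ValueError("De Backer score must be >= 0")

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in _METRIC_FIELDS}

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return _METRIC_FIELDS


@dataclass(frozen=True)
class MacroParams:
    """Macrocirculatory parameters at one time point; any may be missing.

    ``driving_pressure_mmHg`` is derived as MAP − CVP whenever both are
    present, never stored independently.
    """

    sbp_mmHg: Optional[float] = None
    dbp_mmHg: Optional[float] = None
    map_mmHg: Optional[float] = None
    hr_bpm: Optional[float] = None
    cvp_mmHg: Optional[float] = None
    scvo2_pct: Optional[float] = None
    lactate_mmol_per_L: Optional[float] = None

    @property
    def driving_pressure_mmHg(self) -> Optional[float]:
        if self.map_mmHg is None or self.cvp_mmHg is None:
            return None
        return self.map_mmHg - self.cvp_mmHg


@dataclass(frozen=True)
class SubjectRecord:
    """One enrolled subject: arm assignment, covariates, outcome, macro data."""

    subject_id: str
    arm: str
    age_years: float
    charlson: int
    sofa: float
    died_60d_inhospital: bool
    macro: dict[int, MacroParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(
                f"subject {self.subject_id!r}: arm {self.arm!r} not one of "
                f"{ARMS}"
            )
        if self.charlson < 0:
            raise ValueError("Charlson index must be >= 0")
        for tp in self.macro:
            if tp not in TIME_POINTS_H:
                raise ValueError(
                    f"subject {self.subject_id!r}: macro time point {tp} not "
                    f"in {TIME_POINTS_H}"
                )


@dataclass(frozen=True)
class GEEResult:
    """One fitted GEE coefficient with its robust (sandwich) inference."""

    outcome: str
    predictor: str
    family: str
    beta: float
    robust_se: float
    p_value: float
    n_subjects: int
    n_observations: int
    converged: bool = True
    working_correlation: str = "unstructured"
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.n_observations < self.n_subjects:
            raise ValueError("n_observations must be >= n_subjects")


__all__ = [
    "ARMS",
    "TIME_POINTS_H",
    "FlowScore",
    "FieldOfView",
    "VesselSegment",
    "QualityFlags",
    "Clip",
    "MetricSet",
    "MacroParams",
    "SubjectRecord",
    "GEEResult",
    "replace",
]
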