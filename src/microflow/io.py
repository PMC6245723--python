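"""Readers and writers for the trace, metrics and cohort table schemas.

Formats are deliberately plain: one CSV row per traced centerline point
(points of one vessel consecutive, ordered by ``point_index``), a JSON
dialect with one object per clip, and flat CSVs for metrics and cohort
tables.  Missing values are first-class: an empty CSV cell or a JSON
null, never a sentinel number.  Errors name the file, line and field.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ARMS,
    TIME_POINTS_H,
    Clip,
    FieldOfView,
    FlowScore,
    MacroParams,
    MetricSet,
    QualityFlags,
    SubjectRecord,
    VesselSegment,
)

logger = logging.getLogger("microflow")

TRACE_COLUMNS = [
    "clip_id", "subject_id", "time_point_h", "fov_width_um", "fov_height_um",
    "vessel_id", "point_index", "x_um", "y_um", "diameter_um", "flow_score",
    "duration_s", "pressure_artifact", "content_artifact", "out_of_focus",
    "bad_brightness", "unstable",
]

_QUALITY_FLAGS = [
    "pressure_artifact", "content_artifact", "out_of_focus",
    "bad_brightness", "unstable",
]

MACRO_VARS = ["sbp", "dbp", "map", "hr", "cvp", "scvo2", "lactate"]
_MACRO_FIELD = {
    "sbp": "sbp_mmHg", "dbp": "dbp_mmHg", "map": "map_mmHg", "hr": "hr_bpm",
    "cvp": "cvp_mmHg", "scvo2": "scvo2_pct", "lactate": "lactate_mmol_per_L",
}


class SchemaError(ValueError):
    """A table violated its schema; the message names file, line and field."""


def _fail(path, line, field, message) -> None:
    raise SchemaError(f"{path}:{line}: field {field!r}: {message}")


def _parse_bool(raw, path, line, field) -> bool:
    s = str(raw).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no", ""}:
        return False
    _fail(path, line, field, f"not a boolean: {raw!r}")


def read_vessel_traces(path: str | Path) -> list[Clip]:
    """Read traced-vessel files (CSV or the JSON dialect) into clips.

    Unknown columns are ignored with a logged warning; malformed values
    raise :class:`SchemaError` naming the file, line and field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        return _read_traces_json(path)
    return _read_traces_csv(path)


def _read_traces_csv(path: Path) -> list[Clip]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}:1: missing required columns {missing}")
    extra = [c for c in df.columns if c not in TRACE_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)

    clips: list[Clip] = []
    # data line numbers: header is line 1
    df = df.assign(_line=np.arange(2, len(df) + 2))
    for clip_id, group in df.groupby("clip_id", sort=False):
        first = group.iloc[0]
        line0 = int(first["_line"])
        try:
            fov = FieldOfView(float(first["fov_width_um"]),
                              float(first["fov_height_um"]))
        except ValueError as e:
            _fail(path, line0, "fov_width_um/fov_height_um", str(e))
        try:
            time_point = int(first["time_point_h"])
        except ValueError:
            _fail(path, line0, "time_point_h",
                  f"not an integer: {first['time_point_h']!r}")
        quality = QualityFlags(**{
            f: _parse_bool(first[f], path, line0, f) for f in _QUALITY_FLAGS
        })
        vessels = []
        for vessel_id, vgroup in group.groupby("vessel_id", sort=False):
            vline = int(vgroup.iloc[0]["_line"])
            if len(vgroup) < 2:
                _fail(path, vline, "point_index",
                      f"vessel {vessel_id!r} has fewer than 2 centerline points")
            vgroup = vgroup.sort_values(
                "point_index", key=lambda s: s.astype(int)
            )
            for _, row in vgroup.iterrows():
                flow_raw = row["flow_score"]
                try:
                    flow = int(flow_raw)
                except ValueError:
                    _fail(path, int(row["_line"]), "flow_score",
                          f"not an integer: {flow_raw!r}")
                if flow not in (0, 1, 2, 3):
                    _fail(path, int(row["_line"]), "flow_score",
                          f"flow score {flow} outside {{0, 1, 2, 3}}")
            pts = vgroup[["x_um", "y_um"]].astype(float).to_numpy()
            try:
                vessels.append(VesselSegment(
                    vessel_id=str(vessel_id),
                    centerline=pts,
                    diameter_um=float(vgroup.iloc[0]["diameter_um"]),
                    flow=FlowScore(int(vgroup.iloc[0]["flow_score"])),
                ))
            except ValueError as e:
                _fail(path, vline, "centerline/diameter_um", str(e))
        try:
            clips.append(Clip(
                clip_id=str(clip_id),
                subject_id=str(first["subject_id"]),
                time_point_h=time_point,
                fov=fov,
                vessels=tuple(vessels),
                duration_s=float(first["duration_s"]),
                quality=quality,
            ))
        except ValueError as e:
            _fail(path, line0, "clip", str(e))
    return clips


def _read_traces_json(path: Path) -> list[Clip]:
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise SchemaError(f"{path}:1: expected a JSON array of clip objects")
    clips = []
    for i, obj in enumerate(payload):
        where = f"clip #{i}"
        try:
            vessels = []
            for v in obj.get("vessels", []):
                flow = int(v["flow_score"])
                if flow not in (0, 1, 2, 3):
                    raise SchemaError(
                        f"{path}: {where}, vessel {v.get('vessel_id')!r}: "
                        f"flow score {flow} outside {{0, 1, 2, 3}}"
                    )
                vessels.append(VesselSegment(
                    vessel_id=str(v["vessel_id"]),
                    centerline=np.asarray(v["points"], dtype=float),
                    diameter_um=float(v["diameter_um"]),
                    flow=FlowScore(flow),
                ))
            clips.append(Clip(
                clip_id=str(obj["clip_id"]),
                subject_id=str(obj["subject_id"]),
                time_point_h=int(obj["time_point_h"]),
                fov=FieldOfView(float(obj["fov"]["width_um"]),
                                float(obj["fov"]["height_um"])),
                vessels=tuple(vessels),
                duration_s=float(obj.get("duration_s", 0.0)),
                quality=QualityFlags(**{
                    f: bool(obj.get("quality", {}).get(f, False))
                    for f in _QUALITY_FLAGS
                }),
            ))
        except SchemaError:
            raise
        except (KeyError, TypeError, ValueError) as e:
            raise SchemaError(f"{path}: {where}: {e}") from e
    return clips


def write_vessel_traces(clips: Iterable[Clip], path: str | Path) -> None:
    """Write clips to the trace schema (CSV or JSON chosen by suffix)."""
    path = Path(path)
    clips = list(clips)
    if path.suffix.lower() == ".json":
        payload = [{
            "clip_id": c.clip_id,
            "subject_id": c.subject_id,
            "time_point_h": c.time_point_h,
            "fov": {"width_um": c.fov.width_um, "height_um": c.fov.height_um},
            "duration_s": c.duration_s,
            "quality": {f: getattr(c.quality, f) for f in _QUALITY_FLAGS},
            "vessels": [{
                "vessel_id": v.vessel_id,
                "diameter_um": v.diameter_um,
                "flow_score": int(v.flow),
                "points": np.round(v.centerline, 6).tolist(),
            } for v in c.vessels],
        } for c in clips]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    rows = []
    for c in clips:
        for v in c.vessels:
            for k, (x, y) in enumerate(v.centerline):
                rows.append({
                    "clip_id": c.clip_id,
                    "subject_id": c.subject_id,
                    "time_point_h": c.time_point_h,
                    "fov_width_um": c.fov.width_um,
                    "fov_height_um": c.fov.height_um,
                    "vessel_id": v.vessel_id,
                    "point_index": k,
                    "x_um": x,
                    "y_um": y,
                    "diameter_um": v.diameter_um,
                    "flow_score": int(v.flow),
                    "duration_s": c.duration_s,
                    **{f: getattr(c.quality, f) for f in _QUALITY_FLAGS},
                })
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


METRIC_KEYS = ["subject_id", "time_point_h"]


def write_metrics_table(
    metrics: Sequence[tuple],
    path: str | Path,
    clip_level: bool = False,
) -> None:
    """Write one row per observation: ``(subject_id, time_point, MetricSet)``
    tuples (or ``(subject_id, time_point, clip_id, MetricSet)`` when
    ``clip_level``).  Missing values become empty cells; numbers keep 10
    significant digits so a read-back reproduces them.
    """
    rows = []
    for tup in metrics:
        if clip_level:
            subject_id, time_point, clip_id, mset = tup
            row = {"subject_id": subject_id, "time_point_h": time_point,
                   "clip_id": clip_id}
        else:
            subject_id, time_point, mset = tup
            row = {"subject_id": subject_id, "time_point_h": time_point}
        row.update(mset.as_dict())
        rows.append(row)
    keys = METRIC_KEYS + (["clip_id"] if clip_level else [])
    df = pd.DataFrame(rows, columns=keys + list(MetricSet.field_names()))
    df.to_csv(path, index=False, float_format="%.10g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Metrics CSV as a DataFrame; missing cells become NaN."""
    df = pd.read_csv(path)
    for col in METRIC_KEYS:
        if col not in df.columns:
            raise SchemaError(f"{path}:1: missing required column {col!r}")
    return df


def metrics_table_to_sets(df: pd.DataFrame) -> list[tuple[str, int, MetricSet]]:
    out = []
    for _, row in df.iterrows():
        values = {
            name: (None if pd.isna(row[name]) else float(row[name]))
            for name in MetricSet.field_names()
        }
        # densities are structurally non-missing
        values["tvd_mm_per_mm2"] = values["tvd_mm_per_mm2"] or 0.0
        values["pvd_mm_per_mm2"] = values["pvd_mm_per_mm2"] or 0.0
        values["de_backer_n_per_mm"] = values["de_backer_n_per_mm"] or 0.0
        out.append((str(row["subject_id"]), int(row["time_point_h"]),
                    MetricSet(**values)))
    return out


def cohort_columns() -> list[str]:
    cols = ["subject_id", "arm", "age_years", "charlson", "sofa",
            "died_60d_inhospital"]
    for tp in TIME_POINTS_H:
        cols += [f"{v}_{tp}h" for v in MACRO_VARS]
    return cols


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read the per-subject cohort CSV; derives driving pressure from
    MAP − CVP where both are present."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ["subject_id", "arm", "age_years", "charlson", "sofa",
                "died_60d_inhospital"]:
        if col not in df.columns:
            raise SchemaError(f"{path}:1: missing required column {col!r}")
    records = []
    for i, row in df.iterrows():
        line = i + 2
        arm = str(row["arm"])
        if arm not in ARMS:
            _fail(path, line, "arm",
                  f"unknown arm {arm!r}; allowed values are {list(ARMS)}")
        macro = {}
        for tp in TIME_POINTS_H:
            kwargs = {}
            for var in MACRO_VARS:
                col = f"{var}_{tp}h"
                if col in df.columns and not pd.isna(row[col]):
                    kwargs[_MACRO_FIELD[var]] = float(row[col])
            macro[tp] = MacroParams(**kwargs)
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            arm=arm,
            age_years=float(row["age_years"]),
            charlson=int(row["charlson"]),
            sofa=float(row["sofa"]),
            died_60d_inhospital=_parse_bool(
                row["died_60d_inhospital"], path, line, "died_60d_inhospital"
            ),
            macro=macro,
        ))
    return records


def write_cohort(records: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "arm": r.arm,
            "age_years": r.age_years, "charlson": r.charlson, "sofa": r.sofa,
            "died_60d_inhospital": r.died_60d_inhospital,
        }
        for tp, m in r.macro.items():
            for var in MACRO_VARS:
                val = getattr(m, _MACRO_FIELD[var])
                if val is not None:
                    row[f"{var}_{tp}h"] = val
        rows.append(row)
    pd.DataFrame(rows, columns=cohort_columns()).to_csv(
        path, index=False, float_format="%.10g"
    )


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Long-format cohort frame: one row per subject-time-point with macro
    values and the derived driving pressure."""
    rows = []
    for r in records:
        for tp in TIME_POINTS_H:
            m = r.macro.get(tp, MacroParams())
            rows.append({
                "subject_id": r.subject_id, "arm": r.arm,
                "age_years": r.age_years, "charlson": r.charlson,
                "sofa": r.sofa, "died": int(r.died_60d_inhospital),
                "time_point_h": tp,
                "map": m.map_mmHg, "sbp": m.sbp_mmHg, "dbp": m.dbp_mmHg,
                "hr": m.hr_bpm, "cvp": m.cvp_mmHg, "scvo2": m.scvo2_pct,
                "lactate": m.lactate_mmol_per_L,
                "driving_pressure": m.driving_pressure_mmHg,
            })
    return pd.DataFrame(rows)


__all__ = [
    "SchemaError",
    "TRACE_COLUMNS",
    "MACRO_VARS",
    "read_vessel_traces",
    "write_vessel_traces",
    "write_metrics_table",
    "read_metrics_table",
    "metrics_table_to_sets",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "cohort_columns",
]
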