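"""Synthetic vessel networks and cohorts with the study's design structure.

No raw sublingual videos from the parent trial were ever deposited, so
every downstream stage is exercised on simulated data whose *latent*
structure mirrors the repeated-measures design: ~207 subjects randomized
to three resuscitation arms, imaged at 6, 24 and 72 h with up to three
clips per time point, ~19% in-hospital mortality, survivor/nonsurvivor
density differences concentrated at 72 h, and realistic missingness
(non-attempted and quality-failed time points).

Two levels of simulation are provided:

* :func:`generate_clip` / :func:`generate_cohort` build actual traced
  vessel networks, so the full geometry → metrics → analysis pipeline runs
  end to end.  Small-vessel centerlines are tortuosity-controlled random
  walks confined to the field of view, laid down until the total
  centerline length hits the density target exactly, which makes the
  generator calibrated by construction: the pipeline-computed TVD of a
  clip equals its target up to floating-point error.
* :func:`simulate_metrics_cohort` draws subject-time metric values
  directly from the same latent model (no geometry), for the many-replicate
  calibration studies of the analysis stage.

Determinism: every function takes a seed; subject and clip substreams are
keyed by index (master seed → subject → clip), so adding a subject does
not perturb the draws of the others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as mio
from .geometry import quadrant_of_point
from .model import (
    ARMS,
    TIME_POINTS_H,
    Clip,
    FieldOfView,
    FlowScore,
    MacroParams,
    QualityFlags,
    SubjectRecord,
    VesselSegment,
)

DEFAULT_FOV = FieldOfView(1000.0, 750.0)


# --------------------------------------------------------------------------
# single-clip vessel networks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkParams:
    """Controls one clip's vessel network.

    ``target_tvd_mm_per_mm2`` is hit exactly (the last vessel is truncated
    to land on the length budget).  ``ppv_target`` is the per-vessel
    perfusion probability, so the expected length-weighted PPV equals it.
    ``flow_score_probs`` are marginal probabilities of scores 0..3; the
    score is drawn conditionally on the perfusion status (0/1 if not
    perfused, 2/3 if perfused).  ``heterogeneity_boost`` is the
    probability that a randomly chosen quadrant has its vessels' flow
    downshifted by one class, which creates quadrant-mode spread and hence
    nonzero heterogeneity index values.
    """

    target_tvd_mm_per_mm2: float = 22.6
    ppv_target: float = 0.90
    flow_score_probs: tuple[float, float, float, float] = (0.05, 0.05, 0.25, 0.65)
    vessel_length_um: tuple[float, float] = (300.0, 100.0)  # mean, SD
    tortuosity: float = 0.35         # SD of the per-step turning angle (rad)
    step_um: float = 20.0
    n_medium_large: int = 3
    heterogeneity_boost: float = 0.15
    diameter_um: tuple[float, float] = (10.0, 3.0)  # small-vessel mean, SD

    def __post_init__(self) -> None:
        if not self.target_tvd_mm_per_mm2 > 0:
            raise ValueError("target TVD must be positive")
        if not 0.0 <= self.ppv_target <= 1.0:
            raise ValueError("ppv_target must lie in [0, 1]")
        if abs(sum(self.flow_score_probs) - 1.0) > 1e-9:
            raise ValueError("flow_score_probs must sum to 1")
        if self.ppv_target > 0 and self.flow_score_probs[2] + self.flow_score_probs[3] == 0:
            raise ValueError(
                "ppv_target > 0 requires nonzero probability on scores 2-3"
            )
        if self.ppv_target < 1 and self.flow_score_probs[0] + self.flow_score_probs[1] == 0:
            raise ValueError(
                "ppv_target < 1 requires nonzero probability on scores 0-1"
            )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _confined_walk(
    rng: np.random.Generator,
    fov: FieldOfView,
    length_um: float,
    step_um: float,
    tortuosity: float,
) -> np.ndarray:
    """Random walk of exact total length, reflected to stay inside the FOV."""
    w, h = fov.width_um, fov.height_um
    margin = 1e-6
    pos = np.array([rng.uniform(0, w), rng.uniform(0, h)])
    heading = rng.uniform(0.0, 2.0 * math.pi)
    pts = [pos.copy()]
    remaining = length_um
    while remaining > 1e-9:
        s = min(step_um, remaining)
        heading += rng.normal(0.0, tortuosity)
        for _ in range(64):
            cand = pos + s * np.array([math.cos(heading), math.sin(heading)])
            if 0.0 <= cand[0] < w and 0.0 <= cand[1] < h:
                break
            # steer back toward the interior with a little jitter
            cx, cy = w / 2.0 - pos[0], h / 2.0 - pos[1]
            heading = math.atan2(cy, cx) + rng.normal(0.0, 0.5)
        else:  # pragma: no cover - cannot fail for positive-area FOVs
            cand = np.clip(cand, [margin, margin], [w - margin, h - margin])
        pos = cand
        pts.append(pos.copy())
        remaining -= s
    return np.asarray(pts)


def _free_walk(
    rng: np.random.Generator,
    fov: FieldOfView,
    length_um: float,
    step_um: float,
    tortuosity: float,
) -> np.ndarray:
    pos = np.array([rng.uniform(0, fov.width_um), rng.uniform(0, fov.height_um)])
    heading = rng.uniform(0.0, 2.0 * math.pi)
    pts = [pos.copy()]
    remaining = length_um
    while remaining > 1e-9:
        s = min(step_um, remaining)
        heading += rng.normal(0.0, tortuosity)
        pos = pos + s * np.array([math.cos(heading), math.sin(heading)])
        pts.append(pos.copy())
        remaining -= s
    return np.asarray(pts)


def _draw_flow(rng: np.random.Generator, params: NetworkParams) -> FlowScore:
    p = np.asarray(params.flow_score_probs, dtype=float)
    if rng.random() < params.ppv_target:
        probs = p[2:] / p[2:].sum()
        return FlowScore(2 + int(rng.choice(2, p=probs)))
    probs = p[:2] / p[:2].sum()
    return FlowScore(int(rng.choice(2, p=probs)))


def generate_clip(
    params: NetworkParams,
    fov: FieldOfView = DEFAULT_FOV,
    seed: int | np.random.Generator = 0,
    clip_id: str = "clip",
    subject_id: str = "subject",
    time_point_h: int = 6,
) -> Clip:
    """One synthetic clip whose small-vessel TVD equals the target.

    Small-vessel centerlines are confined random walks; vessels are added
    until the cumulative centerline length reaches
    ``target_tvd × FOV area`` with the final vessel truncated to land on
    the budget exactly.  Medium/large vessels (which no metric may use)
    wander freely and may leave the field of view.
    """
    rng = _rng(seed)
    budget_um = params.target_tvd_mm_per_mm2 * fov.width_um * fov.height_um / 1000.0
    mean_len, sd_len = params.vessel_length_um
    vessels: list[VesselSegment] = []
    laid = 0.0
    i = 0
    min_len = max(2.0 * params.step_um, 40.0)
    while budget_um - laid > 1e-6:
        length = float(np.clip(rng.normal(mean_len, sd_len), min_len, 4 * mean_len))
        length = min(length, budget_um - laid)
        if budget_um - laid - length < min_len:
            length = budget_um - laid  # truncate: land exactly on the budget
        pts = _confined_walk(rng, fov, length, params.step_um, params.tortuosity)
        diameter = float(np.clip(rng.normal(*params.diameter_um), 4.0, 19.5))
        vessels.append(VesselSegment(
            vessel_id=f"v{i:03d}", centerline=pts, diameter_um=diameter,
            flow=_draw_flow(rng, params),
        ))
        laid += length
        i += 1
    # quadrant-level flow heterogeneity: one quadrant may flow one class lower
    if params.heterogeneity_boost > 0 and vessels:
        if rng.random() < min(1.0, params.heterogeneity_boost):
            quad = int(rng.integers(0, 4))
            shifted = []
            for v in vessels:
                mid = v.centerline.mean(axis=0)
                x = min(max(mid[0], 0.0), fov.width_um - 1e-9)
                y = min(max(mid[1], 0.0), fov.height_um - 1e-9)
                # downshift within the perfusion class (3->2, 1->0) so the
                # realized PPV still equals the drawn per-vessel status
                if quadrant_of_point(x, y, fov) == quad and int(v.flow) in (1, 3):
                    v = VesselSegment(v.vessel_id, v.centerline, v.diameter_um,
                                      FlowScore(int(v.flow) - 1))
                shifted.append(v)
            vessels = shifted
    for j in range(params.n_medium_large):
        length = float(np.clip(rng.normal(mean_len, sd_len), min_len, 4 * mean_len))
        pts = _free_walk(rng, fov, length, params.step_um, params.tortuosity)
        vessels.append(VesselSegment(
            vessel_id=f"ml{j:02d}", centerline=pts,
            diameter_um=float(rng.uniform(22.0, 70.0)),
            flow=_draw_flow(rng, params),
        ))
    return Clip(
        clip_id=clip_id, subject_id=subject_id, time_point_h=time_point_h,
        fov=fov, vessels=tuple(vessels),
        duration_s=float(rng.uniform(4.0, 9.0)), quality=QualityFlags(),
    )


# --------------------------------------------------------------------------
# cohort-level simulation
# --------------------------------------------------------------------------

def _table(surv, nonsurv):
    return {False: dict(zip(TIME_POINTS_H, surv)),
            True: dict(zip(TIME_POINTS_H, nonsurv))}


# survivor / nonsurvivor TVD mean and SD per time point (mm/mm²)
DEFAULT_TVD = _table(
    surv=[(22.6, 4.2), (23.0, 5.4), (22.1, 4.0)],
    nonsurv=[(21.1, 3.7), (21.7, 5.7), (19.3, 5.1)],
)

# macro-parameter (mean, SD) by died status, pooled over time points
DEFAULT_MACRO = {
    "sbp": {False: (108.7, 14.9), True: (104.9, 14.3)},
    "dbp": {False: (59.3, 8.4), True: (56.8, 9.5)},
    "map": {False: (75.8, 9.3), True: (72.8, 9.5)},
    "hr": {False: (94.3, 17.7), True: (98.2, 19.1)},
    "cvp": {False: (11.8, 5.2), True: (14.0, 5.3)},
    "scvo2": {False: (73.4, 10.7), True: (76.9, 6.1)},
    "lactate": {False: (1.7, 1.2), True: (4.7, 4.5)},
}


@dataclass(frozen=True)
class CohortParams:
    """Study-design parameters of the simulated cohort.

    Defaults reproduce the substudy's conditions: 207 subjects randomized
    1:1:1 to three arms, 19.3% mortality, survivor/nonsurvivor TVD
    means/SDs per time point as observed, ~86% of time points attempted
    with time-point-specific quality pass rates, and 1–3 clips per
    analyzable time point averaging 2.8.  Between-subject heterogeneity
    enters as a Gaussian random effect on the TVD target (fraction
    ``between_subject_icc`` of the total variance) and a logit-normal
    effect on the perfusion probability, inducing the within-subject
    correlation that the GEE working-correlation structure models.
    """

    n_subjects: int = 207
    arm_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    mortality_rate: float = 0.193
    tvd_by_group_time: dict = field(default_factory=lambda: DEFAULT_TVD)
    ppv_by_group: dict = field(
        default_factory=lambda: {False: 0.90, True: 0.90}
    )
    ppv_logit_sd: float = 0.5
    between_subject_icc: float = 0.6
    clip_jitter_sd: float = 1.0
    attempt_rate: float = 0.86
    pass_rate_by_time: dict = field(
        default_factory=lambda: {6: 0.83, 24: 0.75, 72: 0.82}
    )
    clips_per_time_probs: tuple[float, float, float] = (0.05, 0.10, 0.85)
    age_by_group: dict = field(
        default_factory=lambda: {False: (59.4, 16.0), True: (67.2, 12.4)}
    )
    charlson_mean_by_group: dict = field(
        default_factory=lambda: {False: 2.77, True: 4.35}
    )
    sofa_by_group: dict = field(
        default_factory=lambda: {False: (6.96, 3.4), True: (10.83, 3.8)}
    )
    macro_by_group: dict = field(default_factory=lambda: DEFAULT_MACRO)
    fov: FieldOfView = DEFAULT_FOV
    network: NetworkParams = field(default_factory=NetworkParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (*self.arm_probs, self.mortality_rate, self.attempt_rate,
                  *self.pass_rate_by_time.values(), *self.clips_per_time_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")

    @classmethod
    def null_mortality(cls, **kwargs) -> "CohortParams":
        """Variant with no metric–mortality link (group means equalized)."""
        surv = DEFAULT_TVD[False]
        return cls(
            tvd_by_group_time={False: dict(surv), True: dict(surv)},
            ppv_by_group={False: 0.90, True: 0.90},
            **kwargs,
        )


def _subject_seed(master: int, idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=(idx,))


@dataclass
class SimulatedCohort:
    """Everything the simulator produced, plus the latent truth."""

    subjects: list[SubjectRecord]
    clips: dict[tuple[str, int], list[Clip]]   # (subject_id, time_point) -> clips
    missingness: list[dict]                    # dropped time points with reason
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        """Write traces/, cohort.csv and truth.json under ``out_dir``."""
        out = Path(out_dir)
        (out / "traces").mkdir(parents=True, exist_ok=True)
        by_subject: dict[str, list[Clip]] = {}
        for (sid, _tp), cl in sorted(self.clips.items()):
            by_subject.setdefault(sid, []).extend(cl)
        for sid, cl in by_subject.items():
            mio.write_vessel_traces(cl, out / "traces" / f"{sid}.csv")
        mio.write_cohort(self.subjects, out / "cohort.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)


def generate_cohort(params: CohortParams) -> SimulatedCohort:
    """Full cohort of synthetic subjects with traced-vessel clips.

    Survival status influences the traces only through the configured
    group-specific metric parameters; macro parameters are drawn from
    group-conditional Gaussians and are otherwise independent of the
    vessel networks.
    """
    master = params.seed
    subjects: list[SubjectRecord] = []
    clips: dict[tuple[str, int], list[Clip]] = {}
    missing: list[dict] = []
    truth_subjects = []
    total_sd = {
        died: {tp: params.tvd_by_group_time[died][tp][1] for tp in TIME_POINTS_H}
        for died in (False, True)
    }
    for i in range(params.n_subjects):
        srng = np.random.default_rng(_subject_seed(master, i))
        sid = f"S{i:03d}"
        arm = ARMS[int(srng.choice(3, p=params.arm_probs))]
        died = bool(srng.random() < params.mortality_rate)
        age = float(np.clip(srng.normal(*params.age_by_group[died]), 18, 100))
        charlson = int(srng.poisson(params.charlson_mean_by_group[died]))
        sofa = float(np.clip(srng.normal(*params.sofa_by_group[died]), 0, 24))
        # subject-level random effects
        icc = params.between_subject_icc
        tvd_re_z = srng.normal()
        ppv_re = srng.normal(0.0, params.ppv_logit_sd)
        macro = {}
        for tp in TIME_POINTS_H:
            draws = {
                var: float(srng.normal(*params.macro_by_group[var][died]))
                for var in mio.MACRO_VARS
            }
            draws["lactate"] = max(0.1, draws["lactate"])
            draws["cvp"] = max(0.0, draws["cvp"])
            macro[tp] = MacroParams(
                sbp_mmHg=draws["sbp"], dbp_mmHg=draws["dbp"],
                map_mmHg=draws["map"], hr_bpm=draws["hr"],
                cvp_mmHg=draws["cvp"], scvo2_pct=draws["scvo2"],
                lactate_mmol_per_L=draws["lactate"],
            )
        subjects.append(SubjectRecord(
            subject_id=sid, arm=arm, age_years=age, charlson=charlson,
            sofa=sofa, died_60d_inhospital=died, macro=macro,
        ))
        subj_truth = {"subject_id": sid, "died": died, "arm": arm,
                      "tvd_re_z": tvd_re_z, "ppv_re": ppv_re, "targets": {}}
        for t_idx, tp in enumerate(TIME_POINTS_H):
            trng = np.random.default_rng(
                np.random.SeedSequence(master, spawn_key=(i, t_idx))
            )
            if trng.random() >= params.attempt_rate:
                missing.append({"subject_id": sid, "time_point_h": tp,
                                "reason": "not_attempted"})
                continue
            if trng.random() >= params.pass_rate_by_time[tp]:
                missing.append({"subject_id": sid, "time_point_h": tp,
                                "reason": "failed_quality"})
                continue
            mean, sd = params.tvd_by_group_time[died][tp]
            subject_part = math.sqrt(icc) * sd * tvd_re_z
            time_part = trng.normal(0.0, math.sqrt(max(0.0, 1 - icc)) * sd)
            tvd_target_st = max(2.0, mean + subject_part + time_part)
            base_ppv = params.ppv_by_group[died]
            logit = math.log(base_ppv / (1 - base_ppv)) if base_ppv < 1 else 6.0
            ppv_st = 1.0 / (1.0 + math.exp(-(logit + ppv_re)))
            n_clips = 1 + int(trng.choice(3, p=params.clips_per_time_probs))
            subj_truth["targets"][str(tp)] = {
                "tvd": tvd_target_st, "ppv": ppv_st, "n_clips": n_clips,
            }
            cl = []
            for k in range(n_clips):
                crng = np.random.default_rng(
                    np.random.SeedSequence(master, spawn_key=(i, t_idx, k))
                )
                tvd_clip = max(2.0, crng.normal(tvd_target_st,
                                                params.clip_jitter_sd))
                net = NetworkParams(
                    target_tvd_mm_per_mm2=tvd_clip,
                    ppv_target=ppv_st,
                    flow_score_probs=params.network.flow_score_probs,
                    vessel_length_um=params.network.vessel_length_um,
                    tortuosity=params.network.tortuosity,
                    step_um=params.network.step_um,
                    n_medium_large=params.network.n_medium_large,
                    heterogeneity_boost=params.network.heterogeneity_boost,
                    diameter_um=params.network.diameter_um,
                )
                cl.append(generate_clip(
                    net, params.fov, seed=crng,
                    clip_id=f"{sid}_t{tp}_c{k}", subject_id=sid,
                    time_point_h=tp,
                ))
            clips[(sid, tp)] = cl
        truth_subjects.append(subj_truth)
    truth = {
        "seed": master,
        "params": {
            "n_subjects": params.n_subjects,
            "mortality_rate": params.mortality_rate,
            "attempt_rate": params.attempt_rate,
            "pass_rate_by_time": params.pass_rate_by_time,
            "between_subject_icc": params.between_subject_icc,
            "tvd_by_group_time": {
                str(k): {str(t): list(v) for t, v in d.items()}
                for k, d in params.tvd_by_group_time.items()
            },
        },
        "subjects": truth_subjects,
        "missingness": missing,
    }
    return SimulatedCohort(subjects=subjects, clips=clips,
                           missingness=missing, truth=truth)


def apply_missingness(
    observations: Sequence[tuple[str, int]],
    attempt_rate: float,
    pass_rate_by_time: dict[int, float],
    seed: int,
) -> tuple[list[tuple[str, int]], list[dict]]:
    """Thin subject-time points by the attempt and quality-pass rates.

    Returns the kept (subject, time) pairs and a record of each dropped
    pair with its reason (``not_attempted`` or ``failed_quality``).
    """
    if not 0.0 <= attempt_rate <= 1.0:
        raise ValueError("attempt_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kept, dropped = [], []
    for sid, tp in observations:
        if rng.random() >= attempt_rate:
            dropped.append({"subject_id": sid, "time_point_h": tp,
                            "reason": "not_attempted"})
        elif rng.random() >= pass_rate_by_time.get(tp, 1.0):
            dropped.append({"subject_id": sid, "time_point_h": tp,
                            "reason": "failed_quality"})
        else:
            kept.append((sid, tp))
    return kept, dropped


# --------------------------------------------------------------------------
# metrics-level simulator (no geometry) for analysis-stage calibration
# --------------------------------------------------------------------------

def simulate_metrics_cohort(params: CohortParams, seed: Optional[int] = None):
    """Subject-time metric table drawn from the latent model directly.

    Skips vessel generation entirely: TVD comes from the same Gaussian
    random-effect model the network generator targets, PPV from the
    logit-normal model, PVD = PPV × TVD, MFI from a truncated skewed
    distribution, and the heterogeneity index from a zero-inflated gamma
    (matching its real abundance of exact zeros).  Used for the
    many-replicate type-I-error and power studies of the analysis stage,
    where building thousands of full vessel networks would add nothing.

    Returns ``(metrics_df, cohort_records)``.
    """
    import pandas as pd

    master = params.seed if seed is None else seed
    cohort_p = params
    rows = []
    subjects = []
    for i in range(cohort_p.n_subjects):
        srng = np.random.default_rng(_subject_seed(master, i))
        sid = f"S{i:03d}"
        arm = ARMS[int(srng.choice(3, p=cohort_p.arm_probs))]
        died = bool(srng.random() < cohort_p.mortality_rate)
        age = float(np.clip(srng.normal(*cohort_p.age_by_group[died]), 18, 100))
        charlson = int(srng.poisson(cohort_p.charlson_mean_by_group[died]))
        sofa = float(np.clip(srng.normal(*cohort_p.sofa_by_group[died]), 0, 24))
        icc = cohort_p.between_subject_icc
        tvd_re_z = srng.normal()
        ppv_re = srng.normal(0.0, cohort_p.ppv_logit_sd)
        mfi_re = srng.normal(0.0, 0.15)
        hi_re = srng.normal(0.0, 0.3)
        macro = {}
        for tp in TIME_POINTS_H:
            draws = {
                var: float(srng.normal(*cohort_p.macro_by_group[var][died]))
                for var in mio.MACRO_VARS
            }
            draws["lactate"] = max(0.1, draws["lactate"])
            draws["cvp"] = max(0.0, draws["cvp"])
            macro[tp] = MacroParams(
                sbp_mmHg=draws["sbp"], dbp_mmHg=draws["dbp"],
                map_mmHg=draws["map"], hr_bpm=draws["hr"],
                cvp_mmHg=draws["cvp"], scvo2_pct=draws["scvo2"],
                lactate_mmol_per_L=draws["lactate"],
            )
        subjects.append(SubjectRecord(
            subject_id=sid, arm=arm, age_years=age, charlson=charlson,
            sofa=sofa, died_60d_inhospital=died, macro=macro,
        ))
        for t_idx, tp in enumerate(TIME_POINTS_H):
            trng = np.random.default_rng(
                np.random.SeedSequence(master, spawn_key=(i, t_idx))
            )
            if trng.random() >= cohort_p.attempt_rate:
                continue
            if trng.random() >= cohort_p.pass_rate_by_time[tp]:
                continue
            mean, sd = cohort_p.tvd_by_group_time[died][tp]
            tvd = max(2.0, mean + math.sqrt(icc) * sd * tvd_re_z
                      + trng.normal(0.0, math.sqrt(max(0.0, 1 - icc)) * sd))
            base_ppv = cohort_p.ppv_by_group[died]
            logit = math.log(base_ppv / (1 - base_ppv)) if base_ppv < 1 else 6.0
            ppv = 1.0 / (1.0 + math.exp(-(logit + ppv_re
                                          + trng.normal(0.0, 0.3))))
            mfi = float(np.clip(trng.normal(2.8 + mfi_re, 0.25), 0.2, 3.0))
            if trng.random() < 0.45:
                hi = 0.0
            else:
                hi = float(trng.gamma(2.0, 0.18) * math.exp(hi_re))
            de_backer = tvd * 0.655 + trng.normal(0.0, 0.8)
            rows.append({
                "subject_id": sid, "time_point_h": tp,
                "tvd_mm_per_mm2": tvd, "pvd_mm_per_mm2": ppv * tvd,
                "ppv_fraction": ppv, "mfi": mfi,
                "heterogeneity_index": hi,
                "de_backer_n_per_mm": max(0.5, de_backer),
            })
    return pd.DataFrame(rows), subjects


__all__ = [
    "DEFAULT_FOV",
    "DEFAULT_TVD",
    "NetworkParams",
    "CohortParams",
    "SimulatedCohort",
    "generate_clip",
    "generate_cohort",
    "apply_missingness",
    "simulate_metrics_cohort",
]
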