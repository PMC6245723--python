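"""GEE-based cohort analysis of the microcirculation metrics.

Marginal regression with subjects as clusters and robust (sandwich)
standard errors, mirroring the study design for repeated sublingual
measurements at 6, 24 and 72 h:

* arm-effect models — does the assigned resuscitation strategy shift a
  metric (EGDT vs usual care, protocolized-noninvasive vs usual care),
  adjusted for age and Charlson index, gated on an arm×time interaction
  check;
* mortality-association models — logistic GEE of 60-day in-hospital
  death on each metric across all time points;
* macro–micro models — each metric regressed on each macrocirculatory
  parameter (MAP, SBP, DBP, HR, CVP, MAP−CVP, lactate);
* descriptive tables for the cohort and for macro parameters by survival.

The family is fixed per outcome: identity-link Gaussian for the
approximately normal densities (TVD, PVD, De Backer), log-link gamma for
the skewed positive MFI and PPV, Tweedie (variance power 1.5, log link)
for the heterogeneity index with its abundance of exact zeros, and
logit-link binomial for mortality.  The working correlation is
unstructured; a fit that fails or does not converge is retried with an
independence working correlation and flagged, never raised — GEE point
estimates remain consistent under working-correlation misspecification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Independence, Unstructured

from .accounting import percent, round_half_up
from .io import cohort_to_frame
from .model import ARMS, TIME_POINTS_H, GEEResult, MetricSet, SubjectRecord

logger = logging.getLogger("microflow")

METRICS = list(MetricSet.field_names())

METRIC_LABEL = {
    "tvd_mm_per_mm2": "TVD (mm/mm2)",
    "pvd_mm_per_mm2": "PVD (mm/mm2)",
    "ppv_fraction": "PPV",
    "mfi": "MFI",
    "heterogeneity_index": "Heterogeneity index",
    "de_backer_n_per_mm": "De Backer score",
}

#: outcome -> GEE family name; asserted fixed by the model registry.
FAMILY_BY_OUTCOME = {
    "tvd_mm_per_mm2": "gaussian_identity",
    "pvd_mm_per_mm2": "gaussian_identity",
    "de_backer_n_per_mm": "gaussian_identity",
    "mfi": "gamma_log",
    "ppv_fraction": "gamma_log",
    "heterogeneity_index": "tweedie",
    "mortality": "binomial_logit",
}

MACRO_PREDICTORS = ["map", "sbp", "dbp", "hr", "cvp", "driving_pressure",
                    "lactate"]

DEFAULT_TWEEDIE_POWER = 1.5
REFERENCE_ARM = "usual_care"


def make_family(name: str, tweedie_power: float = DEFAULT_TWEEDIE_POWER):
    """Instantiate the statsmodels family for a registry name."""
    if name == "gaussian_identity":
        return sm.families.Gaussian()
    if name == "gamma_log":
        return sm.families.Gamma(sm.families.links.Log())
    if name == "tweedie":
        if not 1.0 < tweedie_power < 2.0:
            raise ValueError(
                "Tweedie variance power must lie in (1, 2) to permit exact "
                f"zeros, got {tweedie_power}"
            )
        return sm.families.Tweedie(var_power=tweedie_power,
                                   link=sm.families.links.Log())
    if name == "binomial_logit":
        return sm.families.Binomial()
    raise KeyError(f"unknown family {name!r}")


@dataclass
class _Fit:
    result: object
    converged: bool
    working_correlation: str
    note: str
    n_clusters: int = 0

    def pvalue(self, k: int) -> float:
        """Two-sided Wald p-value for coefficient ``k``.

        The SE is the bias-reduced (Mancl–DeRouen) sandwich estimate:
        the plain sandwich is anticonservative when the number of
        clusters is in the tens, as in per-arm subgroups.
        """
        from scipy import stats

        res = self.result
        z = float(np.asarray(res.params)[k]) / float(np.asarray(res.bse)[k])
        return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _fit_gee(
    data: pd.DataFrame,
    outcome: str,
    exog_cols: Sequence[str],
    family_name: str,
    tweedie_power: float = DEFAULT_TWEEDIE_POWER,
    maxiter: int = 200,
    tol: float = 1e-8,
    working: str = "unstructured",
) -> _Fit:
    """Fit one GEE; degrade to independence working correlation on failure.

    ``working="independence"`` skips the unstructured attempt entirely —
    required for outcomes that are constant within a cluster (the
    mortality models), where a non-diagonal working correlation is
    singular and collapses the estimating equations.
    """
    y = data[outcome].to_numpy(dtype=float)
    X = sm.add_constant(data[list(exog_cols)].astype(float), has_constant="add")
    groups = data["subject_id"].to_numpy()
    time_idx = data["time_point_h"].map(
        {tp: k for k, tp in enumerate(TIME_POINTS_H)}
    ).to_numpy()
    fam = make_family(family_name, tweedie_power)

    n_clusters = int(data["subject_id"].nunique())

    def attempt(cov_struct, label):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(y, X, groups=groups, time=time_idx, family=fam,
                           cov_struct=cov_struct)
            res = model.fit(maxiter=maxiter, ctol=tol,
                            cov_type="bias_reduced")
        converged = bool(getattr(res, "converged", True))
        return _Fit(res, converged, label, "", n_clusters)

    if working == "independence":
        return attempt(Independence(), "independence")
    try:
        fit = attempt(Unstructured(), "unstructured")
        if fit.converged:
            return fit
        note = "unstructured fit did not converge"
    except Exception as e:  # singular/degenerate working correlation
        note = f"unstructured fit failed: {type(e).__name__}"
    logger.warning("%s for outcome %s; falling back to independence "
                   "working correlation", note, outcome)
    fit = attempt(Independence(), "independence")
    fit.note = note
    return fit


def _result_row(
    fit: _Fit, outcome: str, predictor: str, family_name: str,
    data: pd.DataFrame, exog_name: str,
) -> GEEResult:
    res = fit.result
    names = list(res.model.exog_names)
    k = names.index(exog_name)
    return GEEResult(
        outcome=outcome,
        predictor=predictor,
        family=family_name,
        beta=float(np.asarray(res.params)[k]),
        robust_se=float(np.asarray(res.bse)[k]),
        p_value=fit.pvalue(k),
        n_subjects=int(data["subject_id"].nunique()),
        n_observations=int(len(data)),
        converged=fit.converged,
        working_correlation=fit.working_correlation,
        note=fit.note,
    )


def results_to_frame(results: Sequence[GEEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _merged(metrics_df: pd.DataFrame, cohort) -> pd.DataFrame:
    cohort_df = cohort if isinstance(cohort, pd.DataFrame) else \
        cohort_to_frame(cohort)
    df = metrics_df.merge(
        cohort_df, on=["subject_id", "time_point_h"], how="inner",
        suffixes=("", "_cohort"),
    )
    if df.empty:
        raise ValueError("metrics and cohort tables share no subject-time rows")
    return df


def _gamma_safe(df: pd.DataFrame, outcome: str, family_name: str) -> pd.DataFrame:
    """Gamma/Tweedie log-link fits need y > 0 (Tweedie permits exact 0)."""
    if family_name == "gamma_log":
        bad = df[outcome] <= 0
        if bad.any():
            logger.warning("dropping %d non-positive %s values for the "
                           "gamma-log fit", int(bad.sum()), outcome)
            df = df[~bad]
    return df


def fit_arm_effect_models(
    metrics_df: pd.DataFrame,
    cohort,
    interaction_threshold: float = 0.05,
    tweedie_power: float = DEFAULT_TWEEDIE_POWER,
) -> pd.DataFrame:
    """Arm-effect GEE per metric (EGDT and noninvasive, each vs usual care).

    Each model adjusts for age and Charlson index with subject clusters.
    An arm×time interaction model is fitted first; when no interaction
    term reaches ``interaction_threshold`` the main-effects model is
    reported (the repeated-measures convention of reporting the simpler
    model when time does not modify the arm effect).
    """
    df = _merged(metrics_df, cohort)
    present = set(df["arm"].unique())
    missing_arms = [a for a in ARMS if a not in present]
    if missing_arms:
        raise ValueError(
            f"arm contrasts need all three arms; missing {missing_arms}"
        )
    df = df.assign(
        arm_egdt=(df["arm"] == "EGDT").astype(float),
        arm_noninv=(df["arm"] == "protocolized_noninvasive").astype(float),
        time_c=df["time_point_h"].map(
            {tp: k - 1.0 for k, tp in enumerate(TIME_POINTS_H)}
        ),
    )
    df["egdt_x_time"] = df["arm_egdt"] * df["time_c"]
    df["noninv_x_time"] = df["arm_noninv"] * df["time_c"]

    out: list[GEEResult] = []
    for metric in METRICS:
        fam_name = FAMILY_BY_OUTCOME[metric]
        data = df[df[metric].notna()].copy()
        data = _gamma_safe(data, metric, fam_name)
        base_cols = ["arm_egdt", "arm_noninv", "age_years", "charlson"]
        inter_cols = base_cols + ["time_c", "egdt_x_time", "noninv_x_time"]
        fit_i = _fit_gee(data, metric, inter_cols, fam_name, tweedie_power)
        names = list(fit_i.result.model.exog_names)
        inter_p = [
            fit_i.pvalue(names.index(c))
            for c in ("egdt_x_time", "noninv_x_time")
        ]
        if min(inter_p) < interaction_threshold:
            fit, cols = fit_i, inter_cols
            note_extra = "arm x time interaction retained"
        else:
            fit, cols = _fit_gee(data, metric, base_cols, fam_name,
                                 tweedie_power), base_cols
            note_extra = ""
        for exog, label in (("arm_egdt", "EGDT_vs_control"),
                            ("arm_noninv", "noninvasive_vs_control")):
            row = _result_row(fit, metric, label, fam_name, data, exog)
            if note_extra:
                row = GEEResult(**{**row.__dict__,
                                   "note": (row.note + "; " + note_extra).strip("; ")})
            out.append(row)
    return results_to_frame(out)


def fit_mortality_association(
    metrics_df: pd.DataFrame,
    cohort,
    tweedie_power: float = DEFAULT_TWEEDIE_POWER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Logistic GEE of death on each metric, plus per-time-point summaries.

    Returns ``(gee_table, group_summary)``: one GEE row per metric
    (outcome = died across all time points, adjusted for age and Charlson,
    subject clusters, robust SEs), and the survivor/nonsurvivor
    descriptive comparison per time point — mean ± SD for the
    approximately normal densities, median [IQR] for MFI, PPV and the
    heterogeneity index.
    """
    df = _merged(metrics_df, cohort)
    if df["died"].nunique() < 2:
        raise ValueError("mortality models need both survivors and "
                         "nonsurvivors in the cohort")
    out: list[GEEResult] = []
    for metric in METRICS:
        data = df[df[metric].notna()].copy()
        if data.empty or np.isclose(data[metric].std(ddof=0), 0.0):
            out.append(GEEResult(
                outcome="mortality", predictor=metric, family="binomial_logit",
                beta=float("nan"), robust_se=float("nan"), p_value=float("nan"),
                n_subjects=int(data["subject_id"].nunique()) or 1,
                n_observations=max(1, len(data)),
                converged=False, working_correlation="none",
                note="degenerate: metric constant or all missing",
            ))
            continue
        # death is constant within a subject, so any non-diagonal working
        # correlation is singular here: use cluster-robust logistic
        # regression (independence working correlation)
        fit = _fit_gee(data, "died", [metric, "age_years", "charlson"],
                       "binomial_logit", tweedie_power,
                       working="independence")
        out.append(_result_row(fit, "mortality", metric, "binomial_logit",
                               data, metric))

    mean_sd = {"tvd_mm_per_mm2", "pvd_mm_per_mm2", "de_backer_n_per_mm"}
    rows = []
    for metric in METRICS:
        for tp in TIME_POINTS_H:
            for died in (0, 1):
                vals = df[(df["time_point_h"] == tp) & (df["died"] == died)][
                    metric].dropna()
                label = "nonsurvivor" if died else "survivor"
                if len(vals) == 0:
                    summary = ""
                elif metric in mean_sd:
                    summary = f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
                else:
                    q1, med, q3 = vals.quantile([0.25, 0.5, 0.75])
                    summary = f"{med:.2f} [{q1:.2f}–{q3:.2f}]"
                rows.append({
                    "metric": METRIC_LABEL[metric], "time_point_h": tp,
                    "group": label, "n": int(len(vals)), "summary": summary,
                })
    return results_to_frame(out), pd.DataFrame(rows)


def fit_macro_micro_models(
    metrics_df: pd.DataFrame,
    cohort,
    tweedie_power: float = DEFAULT_TWEEDIE_POWER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric-on-macro GEE grid, adjusted for age and Charlson.

    Returns ``(long, grid)``: a tidy table with one row per
    macro-parameter × metric cell, and a pivoted "beta (p)" grid in the
    shape journals print.  Rows with a missing macro value are dropped
    pairwise; an all-missing macro column yields missing cells.
    """
    df = _merged(metrics_df, cohort)
    both = df["map"].notna() & df["cvp"].notna() & df["driving_pressure"].notna()
    if both.any():
        resid = (df.loc[both, "map"] - df.loc[both, "cvp"]
                 - df.loc[both, "driving_pressure"]).abs()
        if resid.max() > 1e-9:
            raise ValueError("driving_pressure column is not MAP - CVP")
    rows = []
    results: list[GEEResult] = []
    for metric in METRICS:
        fam_name = FAMILY_BY_OUTCOME[metric]
        for macro in MACRO_PREDICTORS:
            cell = {"metric": METRIC_LABEL[metric], "macro": macro}
            data = df[df[metric].notna() & df[macro].notna()].copy()
            data = _gamma_safe(data, metric, fam_name)
            if data.empty or data["subject_id"].nunique() < 3:
                cell.update(beta=np.nan, p_value=np.nan, n=0)
                rows.append(cell)
                continue
            fit = _fit_gee(data, metric, [macro, "age_years", "charlson"],
                           fam_name, tweedie_power)
            r = _result_row(fit, metric, macro, fam_name, data, macro)
            results.append(r)
            cell.update(beta=r.beta, p_value=r.p_value, n=r.n_observations)
            rows.append(cell)
    long = pd.DataFrame(rows)
    grid = long.assign(
        text=[
            "" if np.isnan(b) else f"{b:.3f} ({p:.3g})"
            for b, p in zip(long["beta"], long["p_value"])
        ]
    ).pivot(index="metric", columns="macro", values="text")
    grid = grid.reindex(columns=MACRO_PREDICTORS,
                        index=[METRIC_LABEL[m] for m in METRICS])
    return long, grid


def summarize_survivor_macro(cohort) -> pd.DataFrame:
    """Macro parameters by survival, pooled over time points, Welch t-test."""
    from scipy import stats

    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    if df["died"].nunique() < 2:
        raise ValueError("survivor/nonsurvivor comparison needs both classes")
    rows = []
    for macro in ["sbp", "dbp", "map", "hr", "cvp", "scvo2",
                  "driving_pressure", "lactate"]:
        dead = df[df["died"] == 1][macro].dropna()
        alive = df[df["died"] == 0][macro].dropna()
        if len(dead) < 2 or len(alive) < 2:
            rows.append({"parameter": macro, "n_dead": len(dead),
                         "n_alive": len(alive), "dead": "", "alive": "",
                         "p_value": np.nan})
            continue
        p = stats.ttest_ind(dead, alive, equal_var=False).pvalue
        rows.append({
            "parameter": macro,
            "n_dead": int(len(dead)), "n_alive": int(len(alive)),
            "dead": f"{dead.mean():.1f} ± {dead.std(ddof=1):.1f}",
            "alive": f"{alive.mean():.1f} ± {alive.std(ddof=1):.1f}",
            "p_value": float(p),
        })
    return pd.DataFrame(rows)


def descriptive_table(cohort) -> pd.DataFrame:
    """Cohort description by survival: counts (%) and mean (SD) rows."""
    records: Sequence[SubjectRecord]
    if isinstance(cohort, pd.DataFrame):
        per_subject = cohort.drop_duplicates("subject_id")
        df = per_subject.rename(columns={"died": "died_60d_inhospital"})
    else:
        df = pd.DataFrame([{
            "subject_id": r.subject_id, "arm": r.arm,
            "age_years": r.age_years, "charlson": r.charlson, "sofa": r.sofa,
            "died_60d_inhospital": int(r.died_60d_inhospital),
        } for r in cohort])
    groups = {
        "entire_cohort": df,
        "lived": df[df["died_60d_inhospital"] == 0],
        "died": df[df["died_60d_inhospital"] == 1],
    }
    rows = []

    def add(label, fmt):
        rows.append({"characteristic": label,
                     **{g: fmt(sub) for g, sub in groups.items()}})

    add("n", lambda d: f"{len(d)}")
    add("died, n (%)", lambda d: _count_pct(
        int((d["died_60d_inhospital"] == 1).sum()), len(d)))
    for arm in ARMS:
        add(f"arm {arm}, n (%)",
            lambda d, a=arm: _count_pct(int((d["arm"] == a).sum()), len(d)))
    for col, label in (("age_years", "age, years, mean (SD)"),
                       ("charlson", "Charlson index, mean (SD)"),
                       ("sofa", "SOFA, mean (SD)")):
        add(label, lambda d, c=col:
            f"{d[c].mean():.1f} ({d[c].std(ddof=1):.1f})" if len(d) > 1 else "")
    return pd.DataFrame(rows)


def _count_pct(count: int, total: int) -> str:
    if total == 0:
        return "0 (0.0)"
    return f"{count} ({percent(count, total, 1)})"


__all__ = [
    "FAMILY_BY_OUTCOME",
    "MACRO_PREDICTORS",
    "DEFAULT_TWEEDIE_POWER",
    "make_family",
    "fit_arm_effect_models",
    "fit_mortality_association",
    "fit_macro_micro_models",
    "summarize_survivor_macro",
    "descriptive_table",
    "results_to_frame",
]
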