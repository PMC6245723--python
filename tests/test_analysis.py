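import numpy as np
import pandas as pd
import pytest

from microflow import analysis as A
from microflow.io import cohort_to_frame
from microflow.synthetic import CohortParams, simulate_metrics_cohort


@pytest.fixture(scope="module")
def cohort_207():
    """Default-condition cohort: Table-4-patterned survivor/nonsurvivor
    TVD difference, n=207, 19.3% mortality."""
    return simulate_metrics_cohort(CohortParams(n_subjects=207), seed=2024)


@pytest.fixture(scope="module")
def null_cohort():
    return simulate_metrics_cohort(
        CohortParams.null_mortality(n_subjects=120), seed=77)


class TestModelRegistry:
    def test_family_mapping_is_fixed(self):
        assert A.FAMILY_BY_OUTCOME == {
            "tvd_mm_per_mm2": "gaussian_identity",
            "pvd_mm_per_mm2": "gaussian_identity",
            "de_backer_n_per_mm": "gaussian_identity",
            "mfi": "gamma_log",
            "ppv_fraction": "gamma_log",
            "heterogeneity_index": "tweedie",
            "mortality": "binomial_logit",
        }

    def test_tweedie_power_must_allow_exact_zeros(self):
        with pytest.raises(ValueError):
            A.make_family("tweedie", tweedie_power=2.5)
        fam = A.make_family("tweedie", tweedie_power=1.5)
        assert fam.var_power == 1.5


class TestArmEffectModels:
    def test_output_shape_and_families(self, cohort_207):
        metrics_df, subjects = cohort_207
        table = A.fit_arm_effect_models(metrics_df, subjects)
        assert len(table) == 12  # 6 metrics x 2 contrasts
        assert set(table["predictor"]) == {"EGDT_vs_control",
                                           "noninvasive_vs_control"}
        fam = dict(zip(table["outcome"], table["family"]))
        assert fam["mfi"] == "gamma_log"
        assert fam["heterogeneity_index"] == "tweedie"
        assert table["p_value"].between(0, 1).all()
        assert (table["n_observations"] >= table["n_subjects"]).all()

    def test_no_arm_effect_by_construction_rarely_significant(self, cohort_207):
        # the generator assigns arms independently of every metric
        metrics_df, subjects = cohort_207
        table = A.fit_arm_effect_models(metrics_df, subjects)
        assert (table["p_value"] < 0.05).sum() <= 3

    def test_single_arm_input_names_missing_contrast(self, cohort_207):
        metrics_df, subjects = cohort_207
        frame = cohort_to_frame(subjects)
        one_arm = frame[frame["arm"] == "EGDT"]
        kept = metrics_df[metrics_df["subject_id"].isin(one_arm["subject_id"])]
        with pytest.raises(ValueError, match="usual_care"):
            A.fit_arm_effect_models(kept, one_arm)

    def test_injected_mfi_deficit_recovered_with_power(self, null_cohort):
        # multiplicative EGDT deficit on MFI; the gamma-log GEE must find
        # a negative contrast in most replicates
        hits = 0
        reps = 25
        for rep in range(reps):
            metrics_df, subjects = simulate_metrics_cohort(
                CohortParams(n_subjects=200), seed=5000 + rep)
            frame = cohort_to_frame(subjects)
            df = metrics_df.merge(
                frame[["subject_id", "time_point_h", "arm", "age_years",
                       "charlson"]],
                on=["subject_id", "time_point_h"])
            egdt = df["arm"] == "EGDT"
            df.loc[egdt, "mfi"] *= np.exp(-0.15)
            df = df.assign(
                arm_egdt=egdt.astype(float),
                arm_noninv=(df["arm"] == "protocolized_noninvasive").astype(float),
            )
            fit = A._fit_gee(df, "mfi",
                             ["arm_egdt", "arm_noninv", "age_years", "charlson"],
                             "gamma_log")
            names = list(fit.result.model.exog_names)
            k = names.index("arm_egdt")
            beta = np.asarray(fit.result.params)[k]
            p = fit.pvalue(k)
            if beta < 0 and p < 0.05:
                hits += 1
        assert hits >= 0.8 * reps


class TestMortalityAssociation:
    def test_direction_single_replicate(self, cohort_207):
        metrics_df, subjects = cohort_207
        gee, summary = A.fit_mortality_association(metrics_df, subjects)
        row = gee[gee["predictor"] == "tvd_mm_per_mm2"].iloc[0]
        # higher vascular density in survivors => negative log-odds of death
        assert row["beta"] < 0
        assert row["family"] == "binomial_logit"
        assert set(summary["group"]) == {"survivor", "nonsurvivor"}
        assert len(summary) == 6 * 3 * 2

    def test_summary_formats(self, cohort_207):
        metrics_df, subjects = cohort_207
        _, summary = A.fit_mortality_association(metrics_df, subjects)
        tvd = summary[(summary["metric"] == "TVD (mm/mm2)")
                      & (summary["group"] == "survivor")
                      & (summary["time_point_h"] == 6)]["summary"].iloc[0]
        assert "±" in tvd
        mfi = summary[(summary["metric"] == "MFI")
                      & (summary["group"] == "survivor")
                      & (summary["time_point_h"] == 6)]["summary"].iloc[0]
        assert "[" in mfi and "–" in mfi

    def test_constant_metric_flagged_not_crashed(self, cohort_207):
        metrics_df, subjects = cohort_207
        df = metrics_df.copy()
        df["mfi"] = 2.5
        gee, _ = A.fit_mortality_association(df, subjects)
        row = gee[gee["predictor"] == "mfi"].iloc[0]
        assert not row["converged"]
        assert "degenerate" in row["note"]

    def test_single_class_outcome_rejected(self, cohort_207):
        metrics_df, subjects = cohort_207
        survivors = [s for s in subjects if not s.died_60d_inhospital]
        frame = cohort_to_frame(survivors)
        kept = metrics_df[metrics_df["subject_id"].isin(frame["subject_id"])]
        with pytest.raises(ValueError, match="survivors and"):
            A.fit_mortality_association(kept, frame)


class TestMacroMicroModels:
    def test_grid_shape(self, cohort_207):
        metrics_df, subjects = cohort_207
        long, grid = A.fit_macro_micro_models(metrics_df, subjects)
        assert len(long) == 6 * 7
        assert grid.shape == (6, 7)
        assert "driving_pressure" in grid.columns

    def test_injected_cvp_coupling_recovered(self, null_cohort):
        metrics_df, subjects = null_cohort
        frame = cohort_to_frame(subjects)
        df = metrics_df.merge(
            frame[["subject_id", "time_point_h", "cvp"]],
            on=["subject_id", "time_point_h"])
        df["tvd_mm_per_mm2"] = (
            df["tvd_mm_per_mm2"] + 0.4 * (df["cvp"] - df["cvp"].mean())
        ).clip(lower=2.0)
        long, _ = A.fit_macro_micro_models(
            df.drop(columns=["cvp"]), subjects)
        cell = long[(long["macro"] == "cvp")
                    & (long["metric"] == "TVD (mm/mm2)")].iloc[0]
        assert cell["beta"] > 0
        assert cell["p_value"] < 0.05

    def test_corrupted_driving_pressure_rejected(self, cohort_207):
        metrics_df, subjects = cohort_207
        frame = cohort_to_frame(subjects)
        frame = frame.assign(driving_pressure=frame["driving_pressure"] + 5.0)
        with pytest.raises(ValueError, match="MAP - CVP"):
            A.fit_macro_micro_models(metrics_df, frame)

    def test_all_missing_macro_column_gives_missing_cells(self, cohort_207):
        metrics_df, subjects = cohort_207
        frame = cohort_to_frame(subjects)
        frame = frame.assign(lactate=np.nan)
        long, grid = A.fit_macro_micro_models(metrics_df, frame)
        lac = long[long["macro"] == "lactate"]
        assert lac["beta"].isna().all()
        assert (grid["lactate"] == "").all()


class TestDescriptives:
    def test_survivor_macro_lactate_shift_detected(self):
        _, subjects = simulate_metrics_cohort(
            CohortParams(n_subjects=200), seed=31)
        table = A.summarize_survivor_macro(subjects)
        lactate = table[table["parameter"] == "lactate"].iloc[0]
        # configured +3.0 mmol/L nonsurvivor shift is unmistakable at n=200
        assert lactate["p_value"] < 0.001

    def test_missing_rows_excluded_from_n(self, cohort_207):
        _, subjects = cohort_207
        frame = cohort_to_frame(subjects)
        frame.loc[frame.index[:50], "scvo2"] = np.nan
        table = A.summarize_survivor_macro(frame)
        scvo2 = table[table["parameter"] == "scvo2"].iloc[0]
        full = table[table["parameter"] == "map"].iloc[0]
        assert scvo2["n_dead"] + scvo2["n_alive"] == \
            full["n_dead"] + full["n_alive"] - 50

    def test_descriptive_counts_and_percentages(self):
        rows = []
        for i in range(207):
            rows.append({
                "subject_id": f"S{i}", "arm": "EGDT", "died": int(i < 40),
                "age_years": 60.0, "charlson": 3, "sofa": 7.0,
                "time_point_h": 6, "map": 75, "sbp": 105, "dbp": 58,
                "hr": 95, "cvp": 12, "scvo2": 74, "lactate": 2,
                "driving_pressure": 63,
            })
        table = A.descriptive_table(pd.DataFrame(rows))
        died_row = table[table["characteristic"] == "died, n (%)"].iloc[0]
        assert died_row["entire_cohort"] == "40 (19.3)"
        zero_row = table[
            table["characteristic"] == "arm usual_care, n (%)"].iloc[0]
        assert zero_row["entire_cohort"] == "0 (0.0)"
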