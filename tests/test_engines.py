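"""Risk-score engines: normal-value imputation, spec loading, scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from periorisk import (NormalValueTable, impute_normal_values,
                       load_model_spec, score_model)
from periorisk.engines import (RiskModelSpec, derive_model_variables,
                               linear_predictor, possum_physiology_score)
from periorisk.errors import SpecificationError, SpecLoadError
from periorisk.schema import LAB_COLUMNS, PHYSIOLOGY_COLUMNS


@pytest.fixture(scope="module")
def imputed_100k(cohort_100k):
    df, _ = impute_normal_values(cohort_100k)
    return df


class TestImputation:
    def test_single_missing_lab_filled_and_flagged(self, cohort_20k):
        row = cohort_20k.dropna(subset=LAB_COLUMNS).head(1).copy()
        row["sodium"] = np.nan
        out, flags = impute_normal_values(row)
        assert out["sodium"].iloc[0] == 140.0
        assert flags["sodium"].iloc[0]
        assert flags.drop(columns="sodium").iloc[0].sum() == 0

    def test_complete_record_untouched(self, cohort_20k):
        full = cohort_20k.dropna(subset=LAB_COLUMNS).head(10)
        out, flags = impute_normal_values(full)
        pd.testing.assert_frame_equal(out, full)
        assert not flags.to_numpy().any()

    def test_all_labs_missing_scores_minimum_physiology(self, cohort_20k):
        """With every lab imputed to its normal band, the physiological
        sub-score equals what the record's non-lab fields alone dictate."""
        row = cohort_20k.dropna(subset=LAB_COLUMNS).head(1).copy()
        # hand-build the non-lab contribution: young, no flags, normal obs
        row["age_years"] = 50.0
        for flag in ["cardiac_failure", "coronary_artery_disease", "copd"]:
            row[flag] = 0
        row["systolic_bp"], row["pulse"], row["gcs"] = 120.0, 75.0, 15.0
        row["ecg"] = "normal"
        row[LAB_COLUMNS] = np.nan
        out, _ = impute_normal_values(row)
        assert possum_physiology_score(out)[0] == 12  # 12 items x 1 point

    def test_imputation_never_raises_physiology_score(self, cohort_20k):
        """Imputed-normal records score no higher than the same records
        fully observed at the normal defaults."""
        base = cohort_20k.dropna(subset=LAB_COLUMNS).head(200).copy()
        defaults = NormalValueTable().as_dict()
        observed_normal = base.copy()
        for col in PHYSIOLOGY_COLUMNS:
            observed_normal[col] = defaults[col]
        blanked = base.copy()
        blanked[PHYSIOLOGY_COLUMNS[:-1]] = np.nan  # ecg stays categorical
        blanked["ecg"] = None
        imputed, _ = impute_normal_values(blanked)
        assert (possum_physiology_score(imputed)
                <= possum_physiology_score(observed_normal)).all()


class TestScoring:
    def test_intercept_only_spec_is_closed_form(self, cohort_20k):
        spec = RiskModelSpec(name="x", intercept=-7.0, terms=[], variables={})
        p = score_model(cohort_20k.head(5), spec)
        assert np.allclose(p, expit(-7.0))
        assert abs(p[0] - 0.000911) < 5e-7

    def test_all_reference_patient_scores_expit_intercept(self, cohort_20k):
        spec = load_model_spec("sort")
        row = cohort_20k.head(1).copy()
        row["asa_ps"], row["urgency"], row["specialty"] = 1, "elective", "other"
        row["severity"], row["malignancy"], row["age_years"] = "minor", "none", 40.0
        assert np.isclose(score_model(row, spec)[0], expit(spec.intercept))

    def test_agrees_with_handrolled_linear_predictor(self, imputed_100k):
        """Oracle: re-evaluate the spec term-by-term from the derived
        variables, independently of the engine's accumulation."""
        rng = np.random.default_rng(0)
        sample = imputed_100k.iloc[rng.choice(len(imputed_100k), 100,
                                              replace=False)]
        for name in ("sort", "ppossum", "srs"):
            spec = load_model_spec(name)
            mv = derive_model_variables(sample, spec)
            expected = []
            for _, r in mv.iterrows():
                lp = spec.intercept
                for t in spec.terms:
                    if t.linear:
                        lp += t.coef * float(r[t.variable])
                    elif r[t.variable] == t.level:
                        lp += t.coef
                expected.append(1 / (1 + np.exp(-lp)))
            assert np.allclose(score_model(sample, spec), expected,
                               atol=1e-12, rtol=0), name

    def test_sort_median_risk_matches_published_iqr(self, imputed_100k):
        """At generator defaults the SORT-predicted risk distribution sits
        inside the published median [IQR] of 0.4 [0.2, 1.6] percent."""
        p = 100 * score_model(imputed_100k, load_model_spec("sort"))
        assert 0.2 <= np.median(p) <= 1.6

    def test_monotone_in_asa_urgency_and_age(self, cohort_20k):
        spec = load_model_spec("sort")
        row = cohort_20k.head(1).copy()
        for col, values in [("asa_ps", [1, 3, 4, 5]),
                            ("urgency", ["elective", "expedited", "urgent",
                                         "immediate"]),
                            ("age_years", [50, 70, 85])]:
            probe = pd.concat([row] * len(values), ignore_index=True)
            probe[col] = values
            assert np.all(np.diff(score_model(probe, spec)) > 0), col

    def test_unmapped_level_names_variable_and_record(self, cohort_20k):
        spec = load_model_spec("srs")
        row = cohort_20k.head(1).copy()
        row["urgency"] = "warp_speed"
        with pytest.raises(SpecificationError, match="srs_score"):
            score_model(row, spec)


class TestSpecLoading:
    def test_shipped_sort_has_six_variable_groups(self):
        spec = load_model_spec("sort")
        assert len(spec.variables) == 6
        assert {t.variable for t in spec.terms} == set(spec.variables) - set()

    def test_duplicate_term_rejected(self):
        with pytest.raises(SpecLoadError, match="duplicate"):
            RiskModelSpec(
                name="bad", intercept=0.0,
                terms=[t for t in load_model_spec("sort").terms] +
                      [load_model_spec("sort").terms[0]],
                variables=load_model_spec("sort").variables)

    def test_term_without_declared_variable_rejected(self):
        from periorisk.engines import ModelTerm
        with pytest.raises(SpecLoadError, match="undeclared"):
            RiskModelSpec(name="bad", intercept=0.0,
                          terms=[ModelTerm("ghost", 1.0, level="x")],
                          variables={})

    def test_round_trip_save_load(self, tmp_path):
        spec = load_model_spec("ppossum")
        path = tmp_path / "spec.json"
        spec.save(path)
        again = load_model_spec(path)
        assert again.to_dict() == spec.to_dict()

    def test_possum_min_scores(self, cohort_20k):
        """Fully normal elective minor case: physiology 12, operative 6."""
        row = cohort_20k.head(1).copy()
        defaults = NormalValueTable().as_dict()
        for col in PHYSIOLOGY_COLUMNS:
            row[col] = defaults[col]
        row["age_years"] = 50.0
        for flag in ["cardiac_failure", "coronary_artery_disease", "copd"]:
            row[flag] = 0
        row["severity"], row["urgency"], row["malignancy"] = "minor", "elective", "none"
        row["blood_loss"], row["peritoneal_soiling"] = "le_100", "none"
        row["procedure_count"] = "one"
        spec = load_model_spec("ppossum")
        mv = derive_model_variables(row, spec)
        assert mv["possum_physiology"].iloc[0] == 12
        assert mv["possum_operative"].iloc[0] == 6
        lp = linear_predictor(row, spec)[0]
        assert np.isclose(lp, -9.065 + 0.1692 * 12 + 0.155 * 6)
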