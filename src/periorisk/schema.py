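"""Canonical column schema for a perioperative cohort table.

One row is one surgical episode.  Missing values are encoded as NaN (empty
fields in CSV); there are no silent defaults — a consumer either receives a
value or an explicit gap that the normal-value imputation step may fill.
"""

from __future__ import annotations

import pandas as pd

# Ordered categorical levels (order is clinically meaningful where ordinal).
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "urgency": ["elective", "expedited", "urgent", "immediate"],
    "severity": ["minor", "intermediate", "major", "xmajor", "complex"],
    "specialty": [
        "gastrointestinal",
        "gynaecology_urology",
        "neuro_spinal",
        "orthopaedics",
        "thoracic_cardiac",
        "vascular",
        "other",
    ],
    "malignancy": ["none", "primary", "nodal", "metastatic"],
    "diabetes": ["none", "type1", "type2_diet", "type2_oral", "type2_insulin"],
    "ecg": ["normal", "af_60_90", "other_abnormal"],
    "blood_loss": ["le_100", "101_500", "501_999", "ge_1000"],
    "peritoneal_soiling": ["none", "serous", "local_pus", "free_pus_blood_faeces"],
    "procedure_count": ["one", "two", "gt2"],
    "country": ["UK", "ANZ"],
}

# Binary comorbidity flags (0/1).
COMORBIDITY_FLAGS = [
    "coronary_artery_disease",
    "cardiac_failure",
    "dementia",
    "copd",
    "cirrhosis",
    "renal_disease",
]

# How the perioperative team arrived at its risk estimate (0/1 flags; more
# than one may be set).  The last four mark objective-tool assistance.
ASSESSMENT_FLAGS = [
    "am_clinical_judgement",
    "am_asa_ps",
    "am_sort",
    "am_ppossum",
    "am_srs",
    "am_other_tool",
]
OBJECTIVE_TOOL_FLAGS = ["am_sort", "am_ppossum", "am_srs", "am_other_tool"]

# Preoperative blood tests — imputable with normal values when absent.
LAB_COLUMNS = ["haemoglobin", "wbc", "urea", "sodium", "potassium"]
# Bedside physiology — likewise imputable.
PHYSIOLOGY_COLUMNS = LAB_COLUMNS + ["systolic_bp", "pulse", "gcs", "ecg"]

COHORT_FLAGS = ["obstetric", "ambulatory", "under18"]

NUMERIC_COLUMNS = [
    "age_years",
    "asa_ps",
    "systolic_bp",
    "pulse",
    "gcs",
    "haemoglobin",
    "wbc",
    "urea",
    "sodium",
    "potassium",
    "subjective_category",
    "death30_inpatient",
]

ALL_COLUMNS = (
    ["patient_id", "age_years", "sex", "asa_ps", "urgency", "severity",
     "specialty", "malignancy"]
    + COMORBIDITY_FLAGS
    + ["diabetes", "systolic_bp", "pulse", "gcs", "haemoglobin", "wbc",
       "urea", "sodium", "potassium", "ecg", "blood_loss",
       "peritoneal_soiling", "procedure_count", "subjective_category"]
    + ASSESSMENT_FLAGS
    + ["death30_inpatient", "country"]
    + COHORT_FLAGS
)

# Columns that must be populated for an episode to enter the analysis
# cohort (complete-case rule applied AFTER normal-value imputation, so the
# imputable physiology/labs are deliberately absent from this list).
REQUIRED_COLUMNS = [
    "age_years", "sex", "asa_ps", "urgency", "severity", "specialty",
    "malignancy", "subjective_category", "death30_inpatient",
]


def validate_cohort(df: pd.DataFrame, *, require: list[str] | None = None) -> None:
    """Raise ``ValueError`` if *df* does not conform to the episode schema.

    Checks column presence, categorical levels and the ranges of ordinal
    fields; NaN is always an acceptable value (explicit missingness).
    """
    missing_cols = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table is missing columns: {missing_cols}")
    for col, levels in CATEGORICAL_LEVELS.items():
        vals = df[col].dropna()
        bad = set(vals.unique()) - set(levels)
        if bad:
            rows = df.index[df[col].isin(bad)].tolist()[:5]
            raise ValueError(
                f"column {col!r} contains unknown levels {sorted(bad)} "
                f"(first rows: {rows})"
            )
    asa = df["asa_ps"].dropna()
    if len(asa) and not asa.isin([1, 2, 3, 4, 5]).all():
        raise ValueError("asa_ps must be an integer in 1..5")
    subj = df["subjective_category"].dropna()
    if len(subj) and not subj.isin([1, 2, 3, 4, 5, 6]).all():
        raise ValueError("subjective_category must be in 1..6 when present")
    death = df["death30_inpatient"].dropna()
    if len(death) and not death.isin([0, 1]).all():
        raise ValueError("death30_inpatient must be 0/1")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read an episode table from CSV (empty fields -> NaN) and validate."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write an episode table to CSV with missing values as empty fields."""
    df.to_csv(path, index=False, na_rep="")
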