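"""End-to-end study pipeline: exclusions, scoring, and the three
inferential analyses.

Given a raw episode table the pipeline

1. applies the exclusion cascade in a fixed order — eligibility flags
   (obstetric, ambulatory, under-18), then complete-case removal after
   normal-value imputation, then the carve-out of episodes whose risk
   estimate was assisted by an objective tool — logging every count;
2. externally validates SORT, P-POSSUM and SRS on the full analysis cohort
   (calibration + Hosmer–Lemeshow, ROC/AUROC, pairwise DeLong tests);
3. evaluates subjective assessment on the tool-free subcohort (interval
   midpoints, category-wise calibration, polygon ROC, DeLong and
   continuous NRI against SORT);
4. fits the combined subjective+SORT logistic model on the same subcohort,
   bootstrap-corrects its AUROC for optimism, builds the comparison table
   (AUROC/CI/DeLong p and NRI against subjective assessment), runs
   decision-curve analysis for all four predictors and evaluates the
   conditional-probability surface of the combined model.

All randomness (the optimism bootstrap) flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import validation as mv
from .combined import (CombinedModelCoefficients, DEFAULT_SCALE,
                       SubjectiveScale, fit_combined, midpoint_probability,
                       prediction_surface)
from .engines import (NormalValueTable, impute_normal_values,
                      load_model_spec, score_model)
from .errors import ConfigurationError, DomainError
from .schema import (ASSESSMENT_FLAGS, COHORT_FLAGS, OBJECTIVE_TOOL_FLAGS,
                     REQUIRED_COLUMNS, validate_cohort)

MODEL_NAMES = ("sort", "ppossum", "srs")


# ---------------------------------------------------------------------------
# Exclusions


@dataclass
class ExclusionLog:
    n_raw: int
    removed_obstetric: int
    removed_ambulatory: int
    removed_under18: int
    removed_missing: int
    n_validation: int
    removed_tool_assisted: int
    n_subjective_only: int

    def check_balance(self) -> None:
        eligible = (self.n_raw - self.removed_obstetric
                    - self.removed_ambulatory - self.removed_under18)
        assert eligible - self.removed_missing == self.n_validation
        assert (self.n_validation - self.removed_tool_assisted
                == self.n_subjective_only)

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusions(raw: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Exclusion cascade -> (analysis cohort, subjective-only subcohort, log).

    Order is fixed (it changes the counts): eligibility flags first, then
    complete-case on the required non-imputable variables, then the
    objective-tool carve-out.  The carve-out removes episodes whose
    assessment-method flags include any objective risk tool; the remainder
    — clinical judgement and/or ASA-PS alone — form the subcohort for the
    subjective and combined-model analyses.
    """
    validate_cohort(raw)
    n_raw = len(raw)
    flags = raw[COHORT_FLAGS].fillna(0).astype(bool)
    removed_obst = int(flags["obstetric"].sum())
    removed_amb = int((flags["ambulatory"] & ~flags["obstetric"]).sum())
    removed_u18 = int((flags["under18"] & ~flags["obstetric"]
                       & ~flags["ambulatory"]).sum())
    eligible = raw[~flags.any(axis=1)]

    complete = eligible[REQUIRED_COLUMNS].notna().all(axis=1)
    removed_missing = int((~complete).sum())
    cohort = eligible[complete].copy()

    tool = cohort[OBJECTIVE_TOOL_FLAGS].fillna(0).astype(bool).any(axis=1)
    subjective_only = cohort[~tool].copy()

    log = ExclusionLog(
        n_raw=n_raw,
        removed_obstetric=removed_obst,
        removed_ambulatory=removed_amb,
        removed_under18=removed_u18,
        removed_missing=removed_missing,
        n_validation=len(cohort),
        removed_tool_assisted=int(tool.sum()),
        n_subjective_only=len(subjective_only),
    )
    log.check_balance()
    return cohort, subjective_only, log


# ---------------------------------------------------------------------------
# Study configuration and report


@dataclass
class StudyConfig:
    bootstrap_reps: int = 1000
    seed: int = 0
    hl_bins: int = 10
    dca_grid: np.ndarray = field(
        default_factory=lambda: mv.DEFAULT_DCA_GRID.copy())
    surface_sort_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 50.5, 0.5))
    scale: SubjectiveScale = field(default_factory=lambda: DEFAULT_SCALE)
    require_all_categories: bool = True
    min_events_subgroup: int = 20
    normal_values: NormalValueTable = field(default_factory=NormalValueTable)

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        d = json.loads(Path(path).read_text())
        if "dca_grid" in d:
            d["dca_grid"] = np.asarray(d["dca_grid"], dtype=float)
        if "surface_sort_grid" in d:
            d["surface_sort_grid"] = np.asarray(d["surface_sort_grid"],
                                                dtype=float)
        return cls(**d)


@dataclass
class ModelValidationBlock:
    name: str
    calibration: mv.CalibrationResult
    roc: mv.ROCResult
    median_risk_pct: float
    iqr_risk_pct: tuple[float, float]


@dataclass
class StudyReport:
    exclusion_log: ExclusionLog
    cohort_summary: pd.DataFrame
    method_usage: pd.DataFrame
    external_validation: dict[str, ModelValidationBlock]
    delong_pairs: dict[str, mv.DeLongComparison]
    subjective: dict
    combined: dict
    decision_curves: dict[str, mv.DecisionCurve]
    surface: pd.DataFrame
    comparison_table: pd.DataFrame
    metadata: dict

    def to_dict(self) -> dict:
        """JSON-serializable summary (point results; curve data excluded)."""
        ev = {
            name: {
                "auroc": b.roc.auroc, "auroc_ci95": list(b.roc.ci95),
                "hl_statistic": b.calibration.hl_statistic,
                "hl_df": b.calibration.hl_df, "hl_p": b.calibration.hl_p,
                "median_risk_pct": b.median_risk_pct,
                "iqr_risk_pct": list(b.iqr_risk_pct),
            }
            for name, b in self.external_validation.items()
        }
        return {
            "metadata": self.metadata,
            "exclusions": self.exclusion_log.to_dict(),
            "external_validation": ev,
            "delong_pairs": {k: asdict(v) for k, v in self.delong_pairs.items()},
            "subjective": {
                "auroc": self.subjective["roc"].auroc,
                "auroc_ci95": list(self.subjective["roc"].ci95),
                "hl_p": self.subjective["calibration"].hl_p,
                "mortality_rate": self.subjective["mortality_rate"],
            },
            "combined": {
                "coefficients": self.combined["coefficients"].to_dict(),
                "auroc_apparent": self.combined["optimism"].apparent,
                "auroc_corrected": self.combined["optimism"].corrected,
                "optimism": self.combined["optimism"].optimism,
                "B": self.combined["optimism"].B,
                "low_precision": self.combined["optimism"].low_precision,
            },
            "comparison_table": self.comparison_table.to_dict(orient="records"),
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        (out / "exclusion_log.json").write_text(
            json.dumps(self.exclusion_log.to_dict(), indent=2))
        self.cohort_summary.to_csv(out / "table1.csv", index=False)
        self.method_usage.to_csv(out / "table2.csv", index=False)
        self.comparison_table.to_csv(out / "table4_comparisons.csv", index=False)
        pd.DataFrame(self.combined["coefficients"].to_dict()["category_coefs"],
                     index=["coef"]).T.to_csv(out / "coefficients.csv")
        for name, block in self.external_validation.items():
            block.calibration.bins.to_csv(
                out / f"calibration_{name}.csv", index=False)
            pd.DataFrame({"fpr": block.roc.fpr, "tpr": block.roc.tpr}).to_csv(
                out / f"roc_{name}.csv", index=False)
        for name, dc in self.decision_curves.items():
            dc.to_frame().to_csv(out / f"dca_{name}.csv", index=False)
        self.surface.to_csv(out / "combined_surface.csv", index=False)


# ---------------------------------------------------------------------------
# Summaries


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics stratified by 30-day mortality (counts and %)."""
    died = cohort["death30_inpatient"] == 1
    rows = [("n", len(cohort), int((~died).sum()), int(died.sum()))]
    cat_vars = ["sex", "urgency", "severity", "specialty", "malignancy",
                "diabetes"]
    for var in ["asa_ps"] + cat_vars:
        for level, grp in cohort.groupby(var, observed=True):
            rows.append((f"{var}={level}", len(grp),
                         int((grp["death30_inpatient"] == 0).sum()),
                         int((grp["death30_inpatient"] == 1).sum())))
    out = pd.DataFrame(rows, columns=["variable", "overall", "survived", "died"])
    out["overall_pct"] = 100 * out["overall"] / len(cohort)
    return out


def summarize_method_usage(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for flag in ASSESSMENT_FLAGS:
        n = int(cohort[flag].fillna(0).astype(bool).sum())
        rows.append((flag, n, 100 * n / len(cohort)))
    return pd.DataFrame(rows, columns=["method", "n", "pct"])


# ---------------------------------------------------------------------------
# The study


def _validate_model(name: str, pred: np.ndarray, obs: np.ndarray,
                    hl_bins: int) -> ModelValidationBlock:
    pct = 100 * pred
    q = np.percentile(pct, [25, 50, 75])
    return ModelValidationBlock(
        name=name,
        calibration=mv.calibration(pred, obs, n_bins=hl_bins),
        roc=mv.auroc(pred, obs),
        median_risk_pct=float(q[1]),
        iqr_risk_pct=(float(q[0]), float(q[2])),
    )


def _combined_fit_procedure(config: StudyConfig
                            ) -> Callable[[pd.DataFrame], Callable]:
    def fit(train: pd.DataFrame):
        coeffs = fit_combined(
            train, require_all_categories=False)
        def predict(df: pd.DataFrame) -> np.ndarray:
            from .combined import predict_combined
            return predict_combined(
                df["subjective_category"].to_numpy(dtype=int),
                df["sort_percent"].to_numpy(dtype=float), coeffs)
        return predict
    return fit


def run_study(raw: pd.DataFrame, config: StudyConfig | None = None
              ) -> StudyReport:
    """Run the full analysis flow on a raw episode table.

    A table with no flagged or incomplete rows passes the exclusion cascade
    untouched, so pre-cleaned cohorts can be fed in directly.
    """
    config = config or StudyConfig()
    cohort, subj, log = apply_exclusions(raw)

    imputed, _ = impute_normal_values(cohort, config.normal_values)
    obs = imputed["death30_inpatient"].to_numpy(dtype=int)

    preds: dict[str, np.ndarray] = {}
    for name in MODEL_NAMES:
        preds[name] = score_model(imputed, load_model_spec(name))
        imputed[f"{name}_risk"] = preds[name]

    # ---- analysis 1: external validation of the objective tools
    external = {name: _validate_model(name, preds[name], obs, config.hl_bins)
                for name in MODEL_NAMES}
    pairs = {}
    for i, a in enumerate(MODEL_NAMES):
        for b in MODEL_NAMES[i + 1:]:
            pairs[f"{a}_vs_{b}"] = mv.delong_compare(preds[a], preds[b], obs)

    # ---- analysis 2: subjective assessment on the tool-free subcohort
    subj_imp, _ = impute_normal_values(subj, config.normal_values)
    subj_obs = subj_imp["death30_inpatient"].to_numpy(dtype=int)
    subj_cat = subj_imp["subjective_category"].to_numpy(dtype=int)
    subj_mid = midpoint_probability(subj_cat, config.scale)
    sort_subj = score_model(subj_imp, load_model_spec("sort"))
    subj_imp["sort_percent"] = 100 * sort_subj

    subj_block = {
        "n": len(subj_imp),
        "mortality_rate": float(subj_obs.mean()),
        "calibration": mv.calibration(subj_mid, subj_obs, groups=subj_cat),
        "roc": mv.auroc_ordinal(subj_cat, subj_obs),
        "delong_vs_sort": mv.delong_compare(subj_mid, sort_subj, subj_obs),
        "nri_sort_vs_subjective": mv.continuous_nri(subj_mid, sort_subj,
                                                    subj_obs),
    }
    sort_roc_subj = mv.auroc(sort_subj, subj_obs)

    # ---- analysis 3: combined model + optimism + comparisons + DCA
    coeffs = fit_combined(
        subj_imp, require_all_categories=config.require_all_categories)
    from .combined import predict_combined
    comb_pred = predict_combined(subj_cat, subj_imp["sort_percent"].to_numpy(),
                                 coeffs)
    optimism = mv.bootstrap_optimism(
        subj_imp, _combined_fit_procedure(config), mv.auroc_metric,
        B=config.bootstrap_reps, seed=config.seed,
        metric_name="auroc_combined")
    comb_roc = mv.auroc(comb_pred, subj_obs)
    combined_block = {
        "coefficients": coeffs,
        "predictions_roc": comb_roc,
        "calibration": mv.calibration(comb_pred, subj_obs,
                                      n_bins=config.hl_bins),
        "optimism": optimism,
        "delong_vs_subjective": mv.delong_compare(comb_pred, subj_mid,
                                                  subj_obs),
        "nri_vs_subjective": mv.continuous_nri(subj_mid, comb_pred, subj_obs),
    }

    comparison = pd.DataFrame([
        {"model": "clinical", "auroc": subj_block["roc"].auroc,
         "ci_lo": subj_block["roc"].ci95[0],
         "ci_hi": subj_block["roc"].ci95[1],
         "delong_p_vs_clinical": np.nan, "nri_vs_clinical": np.nan,
         "nri_p": np.nan},
        {"model": "sort", "auroc": sort_roc_subj.auroc,
         "ci_lo": sort_roc_subj.ci95[0], "ci_hi": sort_roc_subj.ci95[1],
         "delong_p_vs_clinical": subj_block["delong_vs_sort"].p,
         "nri_vs_clinical": subj_block["nri_sort_vs_subjective"].nri_total,
         "nri_p": subj_block["nri_sort_vs_subjective"].p},
        {"model": "combined", "auroc": optimism.corrected,
         "ci_lo": comb_roc.ci95[0] - optimism.optimism,
         "ci_hi": comb_roc.ci95[1] - optimism.optimism,
         "delong_p_vs_clinical": combined_block["delong_vs_subjective"].p,
         "nri_vs_clinical": combined_block["nri_vs_subjective"].nri_total,
         "nri_p": combined_block["nri_vs_subjective"].p},
    ])

    sort_pred_subj = sort_subj
    dca = {
        "subjective": mv.decision_curve(subj_mid, subj_obs, config.dca_grid),
        "sort": mv.decision_curve(sort_pred_subj, subj_obs, config.dca_grid),
        "ppossum": mv.decision_curve(
            score_model(subj_imp, load_model_spec("ppossum")), subj_obs,
            config.dca_grid),
        "srs": mv.decision_curve(
            score_model(subj_imp, load_model_spec("srs")), subj_obs,
            config.dca_grid),
        "combined": mv.decision_curve(comb_pred, subj_obs, config.dca_grid),
    }

    surface = prediction_surface(coeffs, config.surface_sort_grid)

    return StudyReport(
        exclusion_log=log,
        cohort_summary=summarize_cohort(cohort),
        method_usage=summarize_method_usage(cohort),
        external_validation=external,
        delong_pairs=pairs,
        subjective=subj_block,
        combined=combined_block,
        decision_curves=dca,
        surface=surface,
        comparison_table=comparison,
        metadata={"seed": config.seed, "bootstrap_reps": config.bootstrap_reps,
                  "n_raw": log.n_raw, "n_validation": log.n_validation,
                  "n_subjective_only": log.n_subjective_only},
    )


def run_subgroup(cohort: pd.DataFrame, predicate, config: StudyConfig | None = None,
                 description: str = "") -> StudyReport:
    """Re-run the pipeline on a subgroup.

    *predicate* is either a pandas query string or a callable returning a
    boolean mask.  Subgroups with fewer events than
    ``config.min_events_subgroup`` are refused.  Dummies for the combined
    model are built from the observed categories only (rare top categories
    may be empty within a subgroup).
    """
    config = config or StudyConfig()
    if callable(predicate):
        mask = np.asarray(predicate(cohort), dtype=bool)
        desc = description or getattr(predicate, "__name__", "callable")
    else:
        mask = cohort.eval(predicate).to_numpy(dtype=bool)
        desc = description or str(predicate)
    subset = cohort[mask]
    n_events = int((subset["death30_inpatient"] == 1).sum())
    if n_events < config.min_events_subgroup:
        raise DomainError(
            f"subgroup {desc!r} has {n_events} events "
            f"(< {config.min_events_subgroup}); refusing to run")
    from dataclasses import replace
    sub_config = replace(config, require_all_categories=False)
    report = run_study(subset, sub_config)
    report.metadata["subgroup"] = desc
    return report
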