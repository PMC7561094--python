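"""Prognostic-model validation statistics.

Everything needed to externally validate a binary risk model and to compare
two models on the same patients:

* calibration — decile (or user-grouped) binning of predicted risk with
  Wilson confidence intervals, a lowess-smoothed curve, and the
  Hosmer–Lemeshow chi-square statistic;
* discrimination — AUROC for continuous predictors and for ordinal
  category predictors (whose ROC is a polygon), with DeLong variance and
  normal-approximation confidence intervals;
* DeLong's test for two correlated ROC curves (structural components);
* the continuous net reclassification improvement (NRI) with its
  asymptotic standard error;
* decision-curve analysis net benefit with treat-all / treat-none
  references;
* bootstrap optimism correction for internally validated performance.

Conventions, where the literature admits choices: tied predictions earn
half credit in the AUROC (Mann–Whitney convention); exact ties count as "no
reclassification" in the NRI; the Hosmer–Lemeshow statistic is referred to
chi-square with (bins - 2) degrees of freedom, with the degrees of freedom
reported so readers can re-derive the p-value under other conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError

__all__ = [
    "CalibrationResult", "ROCResult", "DeLongComparison", "NRIResult",
    "DecisionCurve", "OptimismReport",
    "calibration", "auroc", "auroc_ordinal", "delong_compare",
    "continuous_nri", "net_benefit", "decision_curve", "bootstrap_optimism",
]


def _check_binary(obs: np.ndarray) -> np.ndarray:
    obs = np.asarray(obs)
    vals = set(np.unique(obs).tolist())
    if not vals <= {0, 1, 0.0, 1.0, False, True}:
        raise DomainError("outcome must be binary 0/1")
    obs = obs.astype(bool)
    if obs.all() or not obs.any():
        raise DomainError("both outcome classes must be present")
    return obs


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationResult:
    bins: pd.DataFrame           # mean_pred, obs_prop, ci_lo, ci_hi, n, deaths
    hl_statistic: float
    hl_df: int
    hl_p: float
    smoothed: pd.DataFrame | None = None   # pred, obs_smooth
    degenerate: bool = False

    @property
    def n(self) -> int:
        return int(self.bins["n"].sum())


def calibration(pred, obs, n_bins: int = 10, *,
                groups: Sequence | None = None,
                smooth: bool = True,
                lowess_frac: float = 0.3) -> CalibrationResult:
    """Observed-versus-expected calibration with the Hosmer–Lemeshow test.

    Bins are deciles of predicted risk (``pd.qcut``; tied predictions stay
    in one bin, so fewer than *n_bins* bins may result).  Pass *groups* to
    bin by a precomputed label instead — e.g. the subjective category when
    the predictor is an interval midpoint.  The HL statistic is
    sum((O - E)^2 / (E (1 - E/n))) over bins against chi-square with
    ``bins - 2`` degrees of freedom.

    A predictor with a single distinct value yields a single-bin result
    flagged ``degenerate`` with an undefined (NaN) HL statistic.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise DomainError("pred and obs must have equal length")
    if np.any((pred < 0) | (pred > 1) | np.isnan(pred)):
        raise DomainError("predictions must lie in [0, 1]")

    if groups is not None:
        labels = pd.Series(np.asarray(groups), name="bin")
    elif len(np.unique(pred)) == 1:
        labels = pd.Series(np.zeros(len(pred), dtype=int), name="bin")
    else:
        labels = pd.Series(
            pd.qcut(pred, q=n_bins, labels=False, duplicates="drop"),
            name="bin")

    g = pd.DataFrame({"pred": pred, "obs": obs, "bin": labels}).groupby("bin")
    tab = g.agg(mean_pred=("pred", "mean"), deaths=("obs", "sum"),
                n=("obs", "size")).reset_index()
    tab["obs_prop"] = tab["deaths"] / tab["n"]
    ci = [proportion_confint(d, n, alpha=0.05, method="wilson")
          for d, n in zip(tab["deaths"], tab["n"])]
    tab["ci_lo"] = [c[0] for c in ci]
    tab["ci_hi"] = [c[1] for c in ci]
    tab = tab.sort_values("mean_pred").reset_index(drop=True)

    k = len(tab)
    degenerate = k < 3
    if degenerate and k == 1:
        hl_stat, df_, p = float("nan"), 0, float("nan")
    else:
        E = (tab["mean_pred"] * tab["n"]).to_numpy()
        O = tab["deaths"].to_numpy()
        nn = tab["n"].to_numpy()
        denom = E * (1.0 - E / nn)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(denom > 0, (O - E) ** 2 / denom, np.inf)
        hl_stat = float(contrib.sum())
        df_ = max(k - 2, 1)
        p = float(stats.chi2.sf(hl_stat, df_))

    smoothed = None
    if smooth and not degenerate and len(np.unique(pred)) > 10:
        sm_xy = sm.nonparametric.lowess(obs, pred, frac=lowess_frac,
                                        delta=0.005 * np.ptp(pred))
        smoothed = pd.DataFrame(sm_xy, columns=["pred", "obs_smooth"])

    return CalibrationResult(bins=tab, hl_statistic=hl_stat, hl_df=df_,
                             hl_p=p, smoothed=smoothed, degenerate=degenerate)


# ---------------------------------------------------------------------------
# ROC / AUROC / DeLong


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    variance: float          # DeLong estimator
    ci95: tuple[float, float]
    predictor_kind: str      # "continuous" | "ordinal"

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _roc_points(pred: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Operating points (FPR, TPR), one per distinct threshold, sorted by
    FPR, anchored at (0,0) and (1,1)."""
    order = np.argsort(-pred, kind="mergesort")
    y = obs[order]
    p = pred[order]
    distinct = np.r_[np.nonzero(np.diff(p))[0], len(p) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tp / obs.sum()]
    fpr = np.r_[0.0, fp / (~obs).sum()]
    return fpr, tpr


def _delong_components(preds: np.ndarray, obs: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Structural components V10 (cases) and V01 (controls) per predictor.

    Midrank formulation: for cases x_i, V10_i = (R_i - r_i) / n_controls
    where R_i is the midrank of x_i in the pooled sample and r_i within the
    cases; symmetrically for controls.  Mean of V10 (or 1 - mean V01)
    recovers the ties-half AUROC.
    """
    preds = np.atleast_2d(np.asarray(preds, dtype=float))
    cases = preds[:, obs]
    controls = preds[:, ~obs]
    m, n = cases.shape[1], controls.shape[1]
    k = preds.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for i in range(k):
        all_r = rankdata(np.r_[cases[i], controls[i]])
        case_r = rankdata(cases[i])
        ctrl_r = rankdata(controls[i])
        v10[i] = (all_r[:m] - case_r) / n
        v01[i] = 1.0 - (all_r[m:] - ctrl_r) / m
        aucs[i] = v10[i].mean()
    return aucs, v10, v01


def auroc(pred, obs, *, predictor_kind: str = "continuous") -> ROCResult:
    """AUROC with DeLong variance and 95% CI.

    The area equals the Mann–Whitney statistic with ties given half credit,
    which in turn equals the trapezoidal area under the operating points.
    """
    pred = np.asarray(pred, dtype=float)
    obs = _check_binary(obs)
    if len(pred) != len(obs):
        raise DomainError("pred and obs must have equal length")
    aucs, v10, v01 = _delong_components(pred, obs)
    auc = float(aucs[0])
    m, n = int(obs.sum()), int((~obs).sum())
    var = float(np.var(v10[0], ddof=1) / m + np.var(v01[0], ddof=1) / n) \
        if min(m, n) > 1 else float("nan")
    se = np.sqrt(var) if var == var else float("nan")
    ci = (max(0.0, auc - 1.959963984540054 * se),
          min(1.0, auc + 1.959963984540054 * se)) if se == se else (float("nan"),) * 2
    fpr, tpr = _roc_points(pred, obs)
    return ROCResult(fpr=fpr, tpr=tpr, auroc=auc, variance=var, ci95=ci,
                     predictor_kind=predictor_kind)


def auroc_ordinal(categories, obs) -> ROCResult:
    """AUROC of an ordinal category predictor.

    The ROC has one operating point per category threshold (a polygon);
    its trapezoidal area equals the ties-half Mann–Whitney statistic on the
    category ranks, which is asserted internally.
    """
    cat = np.asarray(categories, dtype=float)
    if len(np.unique(cat)) < 2:
        raise DomainError("need at least 2 distinct categories")
    res = auroc(cat, obs, predictor_kind="ordinal")
    area = float(np.trapezoid(res.tpr, res.fpr))
    assert abs(area - res.auroc) < 1e-12, "polygon area != Mann-Whitney AUROC"
    return res


@dataclass
class DeLongComparison:
    auroc_a: float
    auroc_b: float
    z: float
    p: float
    variance_diff: float


def delong_compare(pred_a, pred_b, obs) -> DeLongComparison:
    """DeLong's test for two correlated ROC curves on the same records.

    Two-sided normal test of AUROC(a) - AUROC(b) using the structural-
    components covariance.  A zero-variance difference (e.g. identical
    predictors) reports z = 0, p = 1.
    """
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    obs = _check_binary(obs)
    if not (len(pred_a) == len(pred_b) == len(obs)):
        raise DomainError("predictors and outcome must share length")
    aucs, v10, v01 = _delong_components(np.vstack([pred_a, pred_b]), obs)
    m, n = int(obs.sum()), int((~obs).sum())
    # a single case (or control) contributes no estimable variance
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = float(s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + float(s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var = max(var, 0.0)
    diff = float(aucs[0] - aucs[1])
    if var <= 0 or abs(diff) < 1e-15:
        z = 0.0 if abs(diff) < 1e-15 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return DeLongComparison(auroc_a=float(aucs[0]), auroc_b=float(aucs[1]),
                            z=float(z), p=p, variance_diff=var)


# ---------------------------------------------------------------------------
# Continuous NRI


@dataclass
class NRIResult:
    nri_events: float
    nri_nonevents: float
    nri_total: float
    se: float
    z: float
    p: float


def continuous_nri(pred_old, pred_new, obs) -> NRIResult:
    """Continuous net reclassification improvement, new versus old model.

    events component   = P(new > old | event)    - P(new < old | event)
    nonevents component = P(new < old | nonevent) - P(new > old | nonevent)

    Exact ties count in neither direction.  The standard error is the
    asymptotic multinomial formula; z and the two-sided p test NRI = 0.
    """
    old = np.asarray(pred_old, dtype=float)
    new = np.asarray(pred_new, dtype=float)
    obs = _check_binary(obs)
    if not (len(old) == len(new) == len(obs)):
        raise DomainError("predictors and outcome must share length")
    up = new > old
    down = new < old

    def _component(mask, sign):
        n = mask.sum()
        p_up = up[mask].mean()
        p_down = down[mask].mean()
        comp = sign * (p_up - p_down)
        var = (p_up + p_down - (p_up - p_down) ** 2) / n
        return comp, var

    nri_e, var_e = _component(obs, +1)
    nri_ne, var_ne = _component(~obs, -1)
    total = nri_e + nri_ne
    se = float(np.sqrt(var_e + var_ne))
    z = total / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return NRIResult(nri_events=float(nri_e), nri_nonevents=float(nri_ne),
                     nri_total=float(total), se=se, z=float(z), p=p)


# ---------------------------------------------------------------------------
# Decision-curve analysis


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_treat_all: np.ndarray

    @property
    def nb_treat_none(self) -> np.ndarray:
        return np.zeros_like(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "nb_model": self.nb_model,
                             "nb_treat_all": self.nb_treat_all,
                             "nb_treat_none": self.nb_treat_none})


DEFAULT_DCA_GRID = np.round(np.arange(0.001, 0.5001, 0.001), 3)


def net_benefit(pred, obs, threshold: float) -> float:
    """Net benefit of labelling ``pred >= threshold`` as high risk:
    TP/n - (FP/n) * t/(1-t)."""
    if not 0 < threshold < 1:
        raise DomainError("threshold must lie strictly inside (0, 1)")
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=bool)
    n = len(pred)
    high = pred >= threshold
    tp = np.sum(high & obs)
    fp = np.sum(high & ~obs)
    return float(tp / n - (fp / n) * threshold / (1 - threshold))


def decision_curve(pred, obs, grid: np.ndarray | None = None) -> DecisionCurve:
    """Net-benefit curve over a threshold grid, with treat-all reference
    (treat-none is identically zero)."""
    grid = DEFAULT_DCA_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise DomainError("thresholds must lie strictly inside (0, 1)")
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=bool)
    n = len(pred)
    # vectorized over the grid: counts above each threshold via sorting
    order = np.argsort(pred, kind="mergesort")
    p_sorted = pred[order]
    cum_events = np.cumsum(obs[order])
    total_events = int(obs.sum())
    idx = np.searchsorted(p_sorted, grid, side="left")
    events_below = np.where(idx > 0, cum_events[np.maximum(idx - 1, 0)], 0)
    tp = total_events - events_below
    fp = (n - idx) - tp
    nb = tp / n - (fp / n) * grid / (1 - grid)
    prev = total_events / n
    nb_all = prev - (1 - prev) * grid / (1 - grid)
    return DecisionCurve(thresholds=grid, nb_model=nb, nb_treat_all=nb_all)


# ---------------------------------------------------------------------------
# Bootstrap optimism correction


@dataclass
class OptimismReport:
    metric_name: str
    apparent: float
    optimism: float
    corrected: float
    B: int
    n_failed: int
    seed: int
    low_precision: bool = False


def bootstrap_optimism(
    cohort: pd.DataFrame,
    fit_procedure: Callable[[pd.DataFrame], Callable[[pd.DataFrame], np.ndarray]],
    metric: Callable[[np.ndarray, np.ndarray], float],
    *,
    outcome_col: str = "death30_inpatient",
    B: int = 1000,
    seed: int = 0,
    metric_name: str = "metric",
    max_failure_frac: float = 0.10,
) -> OptimismReport:
    """Harrell-style bootstrap optimism correction of an apparent metric.

    ``fit_procedure(train)`` returns a predictor ``f(df) -> risks``.  Each
    replicate resamples episodes with replacement, refits, and contributes
    ``metric(on bootstrap sample) - metric(on original cohort)``; the
    corrected value is ``apparent - mean(optimism)``.  Replicates whose fit
    fails are dropped and counted; more than ``max_failure_frac`` failures
    aborts.  Deterministic given *seed*.
    """
    if B < 1:
        raise DomainError("B must be >= 1")
    rng = np.random.default_rng(seed)
    y = cohort[outcome_col].to_numpy()
    model = fit_procedure(cohort)
    apparent = float(metric(model(cohort), y))
    optimisms = []
    n_failed = 0
    n = len(cohort)
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = cohort.iloc[idx]
        try:
            model_b = fit_procedure(boot)
            app_b = metric(model_b(boot), boot[outcome_col].to_numpy())
            test_b = metric(model_b(cohort), y)
        except Exception:
            n_failed += 1
            continue
        optimisms.append(app_b - test_b)
    if n_failed > max_failure_frac * B:
        raise DomainError(
            f"{n_failed}/{B} bootstrap replicates failed to fit")
    opt = float(np.mean(optimisms)) if optimisms else float("nan")
    return OptimismReport(metric_name=metric_name, apparent=apparent,
                          optimism=opt, corrected=apparent - opt,
                          B=B, n_failed=n_failed, seed=seed,
                          low_precision=len(optimisms) < 100)


def auroc_metric(pred: np.ndarray, obs: np.ndarray) -> float:
    """AUROC as a plain float, for use as a bootstrap metric."""
    return auroc(pred, obs).auroc
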