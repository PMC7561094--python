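"""The 6-category subjective risk scale and the combined
subjective + SORT logistic model.

Before surgery the perioperative team places each patient's 30-day death
risk into one of six ordered intervals (<1%, 1%-2.5%, 2.6%-5%, 5.1%-10%,
10.1%-50%, >50%).  For calibration and reclassification work each category
is represented by its interval midpoint; the top, open-ended category has no
printed midpoint and defaults to 75% (midpoint of 50-100), configurable.

The combined model is a plain logistic regression

    logit(R) = b0 + b1(category) + b2 * SORT%

with the subjective category entering as dummies against the reference
"<1%" and the SORT-predicted risk entering **in percent units** (the slope
is "per 1% risk" — feeding a proportion here is the classic unit bug and is
guarded by tests).  Published coefficients are available as
:data:`PUBLISHED_COEFFICIENTS`; :func:`fit_combined` re-estimates them by
unpenalized maximum likelihood on a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .errors import DomainError, FitError

N_CATEGORIES = 6


@dataclass(frozen=True)
class SubjectiveScale:
    """Ordered risk intervals (in percent) with midpoint probabilities."""

    # (lower, upper) bounds of each printed interval, in percent
    bounds_percent: tuple[tuple[float, float], ...] = (
        (0.0, 1.0), (1.0, 2.5), (2.6, 5.0),
        (5.1, 10.0), (10.1, 50.0), (50.0, 100.0),
    )
    top_midpoint: float = 75.0  # percent; ">50%" has no printed midpoint

    @property
    def midpoints(self) -> tuple[float, ...]:
        """Interval midpoints in percent (0.5, 1.75, 3.8, 7.55, 30.05, top)."""
        mids = tuple((lo + hi) / 2 for lo, hi in self.bounds_percent[:-1])
        return mids + (self.top_midpoint,)

    def __post_init__(self) -> None:
        uppers = [hi for _, hi in self.bounds_percent]
        if sorted(uppers) != list(uppers) or \
                len(self.bounds_percent) != N_CATEGORIES:
            raise DomainError("scale intervals must be 6 increasing bands")
        for (lo, hi), m in zip(self.bounds_percent, self.midpoints):
            if not (lo <= m <= hi):
                raise DomainError(f"midpoint {m} outside its interval [{lo},{hi}]")
        if list(self.midpoints) != sorted(self.midpoints):
            raise DomainError("midpoints must be strictly increasing")

    def categorize(self, p) -> np.ndarray:
        """Bin probabilities (0-1 scale) into categories 1-6.

        The printed intervals tile the axis in percent with one-decimal
        gaps (2.5 vs 2.6); for continuous probabilities the effective bin
        edges are the upper bounds, right-exclusive, so 2.55% falls in the
        third category.
        """
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise DomainError("probabilities must lie in [0, 1]")
        edges = np.array([hi for _, hi in self.bounds_percent[:-1]]) / 100.0
        return 1 + (p[..., None] > edges).sum(axis=-1)


DEFAULT_SCALE = SubjectiveScale()


def midpoint_of(category, scale: SubjectiveScale = DEFAULT_SCALE) -> np.ndarray | float:
    """Midpoint of the category's risk interval, in **percent**.

    ``midpoint_of(1) == 0.5`` and ``midpoint_of(2) == 1.75`` reproduce the
    published mapping exactly.
    """
    c = np.asarray(category)
    if np.any(~np.isin(c, np.arange(1, N_CATEGORIES + 1))):
        raise DomainError(f"subjective category must be in 1..{N_CATEGORIES}")
    mids = np.asarray(scale.midpoints)
    out = mids[c - 1]
    return float(out) if np.isscalar(category) else out


def midpoint_probability(category, scale: SubjectiveScale = DEFAULT_SCALE):
    """Midpoint on the probability (0-1) scale, for NRI/DCA use."""
    return np.asarray(midpoint_of(category, scale)) / 100.0


# ---------------------------------------------------------------------------
# Combined model


@dataclass
class CombinedModelCoefficients:
    """Coefficients of logit(R) = b0 + b1(category) + b2 * SORT%.

    ``category_coefs`` holds b1 for categories 2..6 relative to the "<1%"
    reference (which contributes 0).  ``sort_slope`` is per 1% of
    SORT-predicted risk.
    """

    intercept: float
    sort_slope: float
    category_coefs: dict[int, float]
    se: dict[str, float] = field(default_factory=dict)
    provenance: str = "fitted"
    converged: bool = True
    n_obs: int | None = None

    def category_coef(self, category) -> np.ndarray:
        c = np.asarray(category)
        out = np.zeros(c.shape, dtype=float)
        for k, b in self.category_coefs.items():
            out = np.where(c == k, b, out)
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_coefs"] = {str(k): v for k, v in self.category_coefs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CombinedModelCoefficients":
        d = dict(d)
        d["category_coefs"] = {int(k): float(v)
                               for k, v in d["category_coefs"].items()}
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CombinedModelCoefficients":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Published coefficients of the combined model (standard errors alongside).
PUBLISHED_COEFFICIENTS = CombinedModelCoefficients(
    intercept=-6.403,
    sort_slope=0.04028,
    category_coefs={2: 1.487, 3: 2.365, 4: 3.074, 5: 4.156, 6: 5.028},
    se={"intercept": 0.2135, "sort_slope": 0.007049,
        "cat2": 0.2962, "cat3": 0.3177, "cat4": 0.2976,
        "cat5": 0.2852, "cat6": 0.3186},
    provenance="published_table3",
)


def predict_combined(category, sort_percent,
                     coeffs: CombinedModelCoefficients = PUBLISHED_COEFFICIENTS
                     ) -> np.ndarray:
    """Predicted 30-day mortality from subjective category + SORT risk (%).

    Strictly increasing in both inputs whenever the category coefficients
    are increasing and the slope positive (as published).
    """
    c = np.asarray(category)
    s = np.asarray(sort_percent, dtype=float)
    if np.any(~np.isin(c, np.arange(1, N_CATEGORIES + 1))):
        raise DomainError(f"subjective category must be in 1..{N_CATEGORIES}")
    if np.any(s < 0):
        raise DomainError("sort_percent must be non-negative")
    lp = coeffs.intercept + coeffs.category_coef(c) + coeffs.sort_slope * s
    return expit(lp)


def _design_matrix(category: np.ndarray, sort_percent: np.ndarray,
                   categories: list[int]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(category)), np.asarray(sort_percent, dtype=float)]
    names = ["intercept", "sort_slope"]
    for k in categories:
        cols.append((category == k).astype(float))
        names.append(f"cat{k}")
    return np.column_stack(cols), names


def fit_combined(cohort: pd.DataFrame, *,
                 category_col: str = "subjective_category",
                 sort_percent_col: str = "sort_percent",
                 outcome_col: str = "death30_inpatient",
                 require_all_categories: bool = True,
                 ) -> CombinedModelCoefficients:
    """Maximum-likelihood fit of the combined model on a cohort table.

    The cohort must be complete-case for the three columns.  Categories
    enter as dummies against the "<1%" reference; the SORT column must be in
    percent.  With ``require_all_categories`` (default) an unobserved
    category is an error, mirroring a fit on the full scale; subgroup
    analyses may relax this, in which case dummies are built only for the
    observed categories.
    """
    df = cohort[[category_col, sort_percent_col, outcome_col]]
    if df.isna().any().any():
        raise FitError("fit requires complete cases for category, SORT and outcome")
    cat = df[category_col].to_numpy(dtype=int)
    y = df[outcome_col].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise FitError("outcome must be binary 0/1")
    present = set(np.unique(cat))
    if require_all_categories:
        missing = sorted(set(range(1, N_CATEGORIES + 1)) - present)
        if missing:
            raise FitError(f"no observations in subjective categor"
                           f"{'y' if len(missing) == 1 else 'ies'} {missing}")
        dummy_cats = list(range(2, N_CATEGORIES + 1))
    else:
        dummy_cats = sorted(present - {min(present)}) if len(present) > 1 else []
    X, names = _design_matrix(cat, df[sort_percent_col].to_numpy(dtype=float),
                              dummy_cats)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as e:  # statsmodels raises on perfect separation
        raise FitError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", False):
        raise FitError(
            "logistic fit did not converge after "
            f"{res.mle_retvals.get('iterations')} iterations "
            f"(possible separation); trace: {res.mle_retvals}"
        )
    params = dict(zip(names, res.params))
    ses = dict(zip(names, res.bse))
    return CombinedModelCoefficients(
        intercept=params["intercept"],
        sort_slope=params["sort_slope"],
        category_coefs={k: params[f"cat{k}"] for k in dummy_cats},
        se=ses,
        provenance="fitted",
        converged=True,
        n_obs=len(df),
    )


def prediction_surface(coeffs: CombinedModelCoefficients,
                       sort_grid_percent: np.ndarray | None = None
                       ) -> pd.DataFrame:
    """Conditional-probability surface over SORT% x subjective category.

    One row per (category, SORT%) pair — the monotone fan of curves the
    combined model implies.
    """
    if sort_grid_percent is None:
        sort_grid_percent = np.arange(0.0, 50.5, 0.5)
    rows = []
    for c in range(1, N_CATEGORIES + 1):
        p = predict_combined(np.full(len(sort_grid_percent), c),
                             sort_grid_percent, coeffs)
        rows.append(pd.DataFrame({"category": c,
                                  "sort_percent": sort_grid_percent,
                                  "predicted_risk": p}))
    return pd.concat(rows, ignore_index=True)
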