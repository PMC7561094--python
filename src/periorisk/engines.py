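"""Generalized-linear risk-score engines for perioperative mortality.

The engine is model-agnostic: a :class:`RiskModelSpec` names an intercept, a
set of derived model variables (category recodes, numeric bands, POSSUM
integer sub-scores) and a list of coefficient terms.  The three published
30-day mortality models — SORT, P-POSSUM and the Surgical Risk Scale — ship
as versioned JSON specifications under ``periorisk/model_specs/`` with
provenance strings; their coefficients are transcriptions of the original
publications, not refits.

Missing physiology and laboratory values are filled by
:func:`impute_normal_values` with the centre of the no-abnormality POSSUM
band for each item (what a clinician assumes when a test was not indicated),
before any scoring takes place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import SpecificationError, SpecLoadError
from .schema import PHYSIOLOGY_COLUMNS

BUILTIN_SPECS = {"sort": "sort_v1", "ppossum": "ppossum_v1", "srs": "srs_v1"}

_SPEC_SCHEMA_VERSIONS = {1}


@dataclass(frozen=True)
class ModelTerm:
    """One additive contribution to the linear predictor."""

    variable: str
    coef: float
    level: str | None = None   # categorical terms
    linear: bool = False       # coef * value terms (POSSUM/SRS sub-scores)


@dataclass
class RiskModelSpec:
    """A named logistic scoring specification.

    ``variables`` maps each model variable to a derivation rule applied to
    the canonical episode columns; ``terms`` carry the published
    coefficients.  Predicted risk is ``expit(intercept + sum(terms))`` so it
    always lies strictly inside (0, 1).
    """

    name: str
    intercept: float
    terms: list[ModelTerm]
    variables: dict[str, dict[str, Any]]
    provenance: str = ""
    version: str = ""
    link: str = "logit"

    def __post_init__(self) -> None:
        if self.link != "logit":
            raise SpecLoadError(f"unsupported link {self.link!r}")
        seen = set()
        for t in self.terms:
            if t.variable not in self.variables:
                raise SpecLoadError(
                    f"term references undeclared variable {t.variable!r}"
                )
            key = (t.variable, t.level)
            if key in seen:
                raise SpecLoadError(f"duplicate term {key}")
            seen.add(key)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "name": self.name,
            "version": self.version,
            "link": self.link,
            "provenance": self.provenance,
            "intercept": self.intercept,
            "variables": self.variables,
            "terms": [
                {k: v for k, v in asdict(t).items()
                 if not (k == "level" and v is None) and not (k == "linear" and v is False)}
                for t in self.terms
            ],
        }
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _spec_from_dict(d: dict) -> RiskModelSpec:
    version = d.get("schema_version")
    if version not in _SPEC_SCHEMA_VERSIONS:
        raise SpecLoadError(f"unsupported spec schema_version {version!r}")
    try:
        terms = [ModelTerm(variable=t["variable"], coef=float(t["coef"]),
                           level=t.get("level"), linear=bool(t.get("linear", False)))
                 for t in d["terms"]]
        spec = RiskModelSpec(
            name=d["name"], intercept=float(d["intercept"]), terms=terms,
            variables=d["variables"], provenance=d.get("provenance", ""),
            version=d.get("version", ""), link=d.get("link", "logit"),
        )
    except KeyError as e:  # missing required key
        raise SpecLoadError(f"spec is missing required field {e}") from None
    for t in spec.terms:
        if not t.linear and t.level is None:
            raise SpecLoadError(
                f"categorical term for {t.variable!r} lacks a level"
            )
    return spec


def load_model_spec(path_or_name: str | Path) -> RiskModelSpec:
    """Load a spec from a JSON file, or by built-in name (``sort``,
    ``ppossum``, ``srs``)."""
    key = str(path_or_name).lower()
    if key in BUILTIN_SPECS:
        ref = resources.files("periorisk.model_specs") / f"{BUILTIN_SPECS[key]}.json"
        return _spec_from_dict(json.loads(ref.read_text()))
    return _spec_from_dict(json.loads(Path(path_or_name).read_text()))


# ---------------------------------------------------------------------------
# Normal-value imputation


@dataclass(frozen=True)
class NormalValueTable:
    """Per-item defaults used when preoperative physiology is missing.

    Every default sits inside the minimum-score (1-point) band of the
    corresponding POSSUM physiology item, so imputation can never raise a
    sub-score above the fully observed, fully normal record.
    """

    sodium: float = 140.0        # mmol/L
    potassium: float = 4.0       # mmol/L
    urea: float = 5.0            # mmol/L
    haemoglobin: float = 14.0    # g/dL
    wbc: float = 8.0             # 10^9/L
    pulse: float = 75.0          # bpm
    systolic_bp: float = 120.0   # mmHg
    gcs: float = 15.0
    ecg: str = "normal"

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


def impute_normal_values(
    cohort: pd.DataFrame, table: NormalValueTable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing physiology/lab fields with their normal-range defaults.

    Returns the imputed table (a copy) and a boolean flag frame (same index,
    one column per imputable field) recording exactly which cells were
    filled, for audit.
    """
    table = table or NormalValueTable()
    defaults = table.as_dict()
    out = cohort.copy()
    flags = pd.DataFrame(False, index=cohort.index,
                         columns=PHYSIOLOGY_COLUMNS)
    for col in PHYSIOLOGY_COLUMNS:
        miss = out[col].isna()
        flags[col] = miss
        if miss.any():
            out.loc[miss, col] = defaults[col]
    return out, flags


# ---------------------------------------------------------------------------
# Variable derivation


def _fail_unmapped(df: pd.DataFrame, bad: pd.Series, variable: str) -> None:
    rows = df.index[bad][:3].tolist()
    ids = (df.loc[bad, "patient_id"].head(3).tolist()
           if "patient_id" in df.columns else rows)
    raise SpecificationError(
        f"variable {variable!r}: unmapped or missing level(s) in records {ids}"
    )


def _derive_categorical(df, name, vdef):
    src = df[vdef["source"]]
    mapped = src.astype("object").map(lambda v: vdef["map"].get(_key(v)))
    bad = mapped.isna()
    if bad.any():
        _fail_unmapped(df, bad, name)
    return mapped


def _key(v) -> str | None:
    if pd.isna(v):
        return None
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return str(int(v)) if float(v).is_integer() else str(v)
    return str(v)


def _derive_band(df, name, vdef):
    x = df[vdef["source"]].to_numpy(dtype=float)
    if np.isnan(x).any():
        _fail_unmapped(df, pd.Series(np.isnan(x), index=df.index), name)
    idx = np.searchsorted(np.asarray(vdef["edges"], dtype=float), x, side="right")
    levels = np.asarray(vdef["levels"], dtype=object)
    return pd.Series(levels[idx], index=df.index)


def _derive_flag_in(df, name, vdef):
    src = df[vdef["source"]]
    bad = src.isna()
    if bad.any():
        _fail_unmapped(df, bad, name)
    member = src.isin(vdef["levels"])
    return pd.Series(
        np.where(member, vdef["true_level"], vdef["false_level"]),
        index=df.index,
    )


def _derive_score_sum(df, name, vdef):
    total = np.zeros(len(df))
    for comp in vdef["components"]:
        src = df[comp["source"]]
        mapped = src.astype("object").map(lambda v: comp["map"].get(_key(v)))
        bad = mapped.isna()
        if bad.any():
            _fail_unmapped(df, bad, name)
        total += mapped.to_numpy(dtype=float)
    return pd.Series(total, index=df.index)


def _possum_item(df, item, variable):
    kind = item["kind"]
    if kind == "numeric_bands":
        x = df[item["source"]].to_numpy(dtype=float)
        if np.isnan(x).any():
            _fail_unmapped(df, pd.Series(np.isnan(x), index=df.index),
                           f"{variable}.{item['name']}")
        pts = np.empty(len(x))
        pts.fill(np.nan)
        lo = -np.inf
        for band in item["bands"]:
            hi = band.get("hi", np.inf)
            sel = (x >= lo) & (x < hi) & np.isnan(pts)
            pts[sel] = band["points"]
            lo = hi
        return pts
    if kind == "categorical":
        mapped = df[item["source"]].astype("object").map(
            lambda v: item["map"].get(_key(v)))
        bad = mapped.isna()
        if bad.any():
            _fail_unmapped(df, bad, f"{variable}.{item['name']}")
        return mapped.to_numpy(dtype=float)
    if kind == "flags_max":
        pts = np.full(len(df), float(item["default"]))
        # highest triggered rule wins; rules are independent flags
        for rule in sorted(item["rules"], key=lambda r: r["points"]):
            flag = df[rule["flag"]].fillna(0).astype(bool).to_numpy()
            pts = np.where(flag, np.maximum(pts, rule["points"]), pts)
        return pts
    raise SpecLoadError(f"unknown possum item kind {kind!r}")


def _derive_possum_score(df, name, vdef):
    total = np.zeros(len(df))
    for item in vdef["items"]:
        total += _possum_item(df, item, name)
    return pd.Series(total, index=df.index)


_DERIVERS = {
    "categorical": _derive_categorical,
    "band": _derive_band,
    "flag_in": _derive_flag_in,
    "score_sum": _derive_score_sum,
    "possum_score": _derive_possum_score,
}


def derive_model_variables(cohort: pd.DataFrame, spec: RiskModelSpec) -> pd.DataFrame:
    """Resolve every model variable of *spec* against the episode table."""
    out = {}
    for name, vdef in spec.variables.items():
        try:
            deriver = _DERIVERS[vdef["type"]]
        except KeyError:
            raise SpecLoadError(f"unknown variable type {vdef['type']!r}")
        out[name] = deriver(cohort, name, vdef)
    return pd.DataFrame(out, index=cohort.index)


def linear_predictor(cohort: pd.DataFrame, spec: RiskModelSpec) -> np.ndarray:
    """Intercept plus the sum of matched term contributions, per episode."""
    mv = derive_model_variables(cohort, spec)
    lp = np.full(len(cohort), float(spec.intercept))
    for t in spec.terms:
        if t.linear:
            lp += t.coef * mv[t.variable].to_numpy(dtype=float)
        else:
            lp += t.coef * (mv[t.variable].to_numpy() == t.level)
    return lp


def score_model(cohort: pd.DataFrame, spec: RiskModelSpec) -> np.ndarray:
    """Predicted 30-day mortality probability for each episode.

    The cohort must be complete (post normal-value imputation) for every
    field the spec references; an unresolvable level raises
    :class:`SpecificationError` naming the variable and offending records.
    """
    return expit(linear_predictor(cohort, spec))


def possum_physiology_score(cohort: pd.DataFrame,
                            spec: RiskModelSpec | None = None) -> np.ndarray:
    """Convenience accessor for the 12-item physiological sub-score."""
    spec = spec or load_model_spec("ppossum")
    return derive_model_variables(cohort, spec)["possum_physiology"].to_numpy()
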