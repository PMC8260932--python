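"""Exposure, outcome, and analytic-subset construction for lipid-cognition cohorts.

The cohort is carried as a :class:`pandas.DataFrame` with one row per
participant (first non-missing cholesterol measurement).  This module adds
the derived phenotypes used everywhere downstream:

* clinical lipid status from the 2018 ACC/AHA cholesterol guideline cut
  points (at-risk HDL-C: <40 mg/dL for males, <50 mg/dL for females;
  at-risk TC: >=240 mg/dL);
* the Langa-Weir cognitive classification -- a 27-point sum of immediate
  word recall (0-10), delayed word recall (0-10), serial-7 subtraction
  (0-5) and backward counting from 20 (0-2), banded into
  normal (12-27), CIND (7-11) and dementia (0-6);
* the study exclusions (age window, longitudinal dementia-reversal flag,
  proxy respondents) and the four complete-case analytic subsets
  (marker x contrast) used by the observational and instrumental-variable
  models.

The vocabulary score (0-10) is not part of the 27-point total; it enters
only the cognitive-domain regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSubsetError, ValidationError

# Clinical cut points, mg/dL.
HDL_CUTOFF_MALE = 40.0
HDL_CUTOFF_FEMALE = 50.0
TC_CUTOFF = 240.0

# Langa-Weir status bands over the 27-point total (inclusive bounds).
STATUS_BANDS = {
    "dementia": (0, 6),
    "cind": (7, 11),
    "normal": (12, 27),
}

COMPONENT_RANGES = {
    "imm_recall": (0, 10),
    "del_recall": (0, 10),
    "serial7": (0, 5),
    "backward20": (0, 2),
    "vocab": (0, 10),
}

#: Columns a raw cohort table must provide (`vocab`, `hdl`, `tc` may be empty).
REQUIRED_COLUMNS = [
    "id", "age", "sex", "education", "wave", "hdl", "tc", "lipid_med",
    "stroke", "hypertension", "diabetes", "smoking", "drinker", "bmi",
    "pgs_hdl", "pgs_tc", "pgs_cog", "apoe4", "cetp_dosage",
    "pc1", "pc2", "pc3", "pc4", "pc5",
    "imm_recall", "del_recall", "serial7", "backward20", "vocab",
    "prior_dementia_then_normal", "proxy",
]

#: Union of model covariates; analytic subsets are complete-case on these,
#: so every adjustment tier runs on the same N within a subset.
MODEL_COVARIATES = [
    "age", "sex", "education", "lipid_med", "wave",
    "pc1", "pc2", "pc3", "pc4", "pc5",
    "drinker", "stroke", "hypertension", "diabetes", "bmi",
]

SUBSET_LABELS = {
    ("hdl", "cind_vs_normal"): "A",
    ("hdl", "dementia_vs_normal"): "B",
    ("tc", "cind_vs_normal"): "C",
    ("tc", "dementia_vs_normal"): "D",
}

CONTRAST_CASE_LEVEL = {
    "cind_vs_normal": "cind",
    "dementia_vs_normal": "dementia",
}


@dataclass(frozen=True)
class LipidStatus:
    """Clinical classification of a single lipid marker value."""

    marker: str  # "hdl" or "tc"
    level: str | None  # "normal", "at_risk", or None when the value is missing


@dataclass(frozen=True)
class CognitionResult:
    """27-point Langa-Weir total and its three-level status band."""

    total: int
    status: str
    domain_scores: dict = field(default_factory=dict)


@dataclass
class AnalyticCohort:
    """A filtered cohort plus the bookkeeping of how rows were removed."""

    rows: pd.DataFrame
    exclusion_log: dict
    subset_label: str = "all"

    @property
    def n(self) -> int:
        return len(self.rows)


def classify_lipid(marker: str, value: float, sex: str | None = None) -> LipidStatus:
    """Classify one lipid value against the guideline cut points.

    HDL-C is sex-specific (at risk below 40/50 mg/dL for males/females);
    TC is sex-free (at risk at or above 240 mg/dL).  A missing value yields
    ``level=None`` so the row can be dropped downstream rather than erroring.
    """
    marker = marker.lower()
    if marker not in ("hdl", "tc"):
        raise ValidationError(f"unknown lipid marker {marker!r}")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return LipidStatus(marker, None)
    if value <= 0:
        raise ValidationError(f"{marker} must be positive, got {value}")
    if marker == "hdl":
        if sex not in ("male", "female"):
            raise ValidationError("sex is required to classify HDL-C")
        cut = HDL_CUTOFF_MALE if sex == "male" else HDL_CUTOFF_FEMALE
        level = "at_risk" if value < cut else "normal"
    else:
        level = "at_risk" if value >= TC_CUTOFF else "normal"
    return LipidStatus(marker, level)


def score_langa_weir(imm: int, delayed: int, serial7: int, backward: int) -> CognitionResult:
    """Sum the four status components and band the 27-point total.

    Bands: dementia 0-6, CIND 7-11, normal 12-27 (exhaustive and mutually
    exclusive over the integers 0-27).
    """
    components = {
        "imm_recall": imm,
        "del_recall": delayed,
        "serial7": serial7,
        "backward20": backward,
    }
    for name, value in components.items():
        lo, hi = COMPONENT_RANGES[name]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValidationError(f"missing cognition component {name}")
        if value != int(value) or not lo <= value <= hi:
            raise ValidationError(
                f"{name}={value!r} outside its integer range [{lo}, {hi}]"
            )
    total = int(imm) + int(delayed) + int(serial7) + int(backward)
    for status, (lo, hi) in STATUS_BANDS.items():
        if lo <= total <= hi:
            return CognitionResult(total=total, status=status,
                                   domain_scores={k: int(v) for k, v in components.items()})
    raise ValidationError(f"total {total} outside the 27-point scale")  # pragma: no cover


def _lipid_status_series(df: pd.DataFrame, marker: str) -> pd.Series:
    value = df[marker].astype(float)
    if marker == "hdl":
        cut = np.where(df["sex"].to_numpy() == "male", HDL_CUTOFF_MALE, HDL_CUTOFF_FEMALE)
        at_risk = value.to_numpy() < cut
    else:
        at_risk = value.to_numpy() >= TC_CUTOFF
    bad = value.to_numpy() <= 0
    if np.any(bad & ~np.isnan(value.to_numpy())):
        raise ValidationError(f"non-positive {marker} values present")
    out = np.where(at_risk, "at_risk", "normal").astype(object)
    out[np.isnan(value.to_numpy())] = None
    return pd.Series(out, index=df.index, name=f"{marker}_status")


def phenotype_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Attach derived phenotype columns to a raw cohort table.

    Adds ``hdl_status``, ``tc_status`` (clinical levels), ``cog_total`` and
    ``cog_status`` (Langa-Weir), and ``log_tc_hdl`` (log TC/HDL-C ratio,
    NaN when either marker is missing).  Pure: the input frame is not
    modified.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    out = df.copy()
    out["hdl_status"] = _lipid_status_series(out, "hdl")
    out["tc_status"] = _lipid_status_series(out, "tc")

    comps = out[["imm_recall", "del_recall", "serial7", "backward20"]].astype(float)
    for name in comps.columns:
        lo, hi = COMPONENT_RANGES[name]
        vals = comps[name].to_numpy()
        if np.any(np.isnan(vals)) or np.any((vals < lo) | (vals > hi)) or \
                np.any(vals != np.round(vals)):
            raise ValidationError(f"cognition component {name} missing or out of range")
    total = comps.sum(axis=1).astype(int)
    out["cog_total"] = total
    status = np.full(len(out), "normal", dtype=object)
    status[total <= 11] = "cind"
    status[total <= 6] = "dementia"
    out["cog_status"] = status

    with np.errstate(invalid="ignore", divide="ignore"):
        out["log_tc_hdl"] = np.log(out["tc"].astype(float) / out["hdl"].astype(float))
    return out


def apply_exclusions(df: pd.DataFrame) -> AnalyticCohort:
    """Apply the study exclusions in order: age window, dementia reversal, proxy.

    Retains rows with 50 <= age <= 90 (both ends inclusive), no
    prior-dementia-then-normal reversal flag, and self-respondents.  The
    exclusion log counts rows removed by each rule in that order, so the
    counts sum to input minus retained rows.
    """
    log = {"age_window": 0, "dementia_reversal": 0, "proxy": 0}
    keep = df
    age_ok = (keep["age"] >= 50) & (keep["age"] <= 90)
    log["age_window"] = int((~age_ok).sum())
    keep = keep[age_ok]
    rev = keep["prior_dementia_then_normal"].astype(bool)
    log["dementia_reversal"] = int(rev.sum())
    keep = keep[~rev]
    proxy = keep["proxy"].astype(bool)
    log["proxy"] = int(proxy.sum())
    keep = keep[~proxy]
    return AnalyticCohort(rows=keep.reset_index(drop=True), exclusion_log=log)


def analytic_subset(cohort: AnalyticCohort, marker: str, contrast: str) -> AnalyticCohort:
    """Build one of the four complete-case analytic subsets (A-D).

    Keeps rows with a non-missing clinical status on ``marker``, a cognitive
    status in the contrast's two levels (case level vs normal), and complete
    data on every model covariate.  Using the covariate union keeps N
    constant across adjustment tiers within a subset.
    """
    marker = marker.lower()
    if (marker, contrast) not in SUBSET_LABELS:
        raise ValidationError(f"unknown subset {(marker, contrast)!r}")
    case_level = CONTRAST_CASE_LEVEL[contrast]
    df = cohort.rows
    log = dict(cohort.exclusion_log)

    status_col = f"{marker}_status"
    has_marker = df[status_col].notna()
    log[f"missing_{marker}"] = int((~has_marker).sum())
    df = df[has_marker]

    in_contrast = df["cog_status"].isin(["normal", case_level])
    log["outside_contrast"] = int((~in_contrast).sum())
    df = df[in_contrast]

    complete = df[MODEL_COVARIATES].notna().all(axis=1)
    log["incomplete_covariates"] = int((~complete).sum())
    df = df[complete]

    cells = pd.crosstab(df[status_col], df["cog_status"])
    if cells.shape != (2, 2) or (cells.to_numpy() < 2).any():
        raise DegenerateSubsetError(
            f"subset {SUBSET_LABELS[(marker, contrast)]} has fewer than 2 rows "
            f"in some exposure-outcome cell:\n{cells}"
        )
    return AnalyticCohort(rows=df.reset_index(drop=True), exclusion_log=log,
                          subset_label=SUBSET_LABELS[(marker, contrast)])
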