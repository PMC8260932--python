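"""Instrumental-variable machinery: Wald ratio, strength, heterogeneity.

Single-instrument Mendelian randomization with a standardized polygenic
score (or a 0/1/2 SNP dosage) as the instrument.  Both stages are logistic
models fitted on the identical analytic subset and covariate tier: the
instrument-exposure stage regresses the at-risk clinical status on the
instrument, the instrument-outcome stage regresses the case status on the
instrument.  The ratio of the two instrument coefficients is the Wald-type
estimate of the causal log-odds ratio for the at-risk vs normal exposure
contrast; its uncertainty uses the first-order delta method with zero
cross-covariance between the stages (the standard single-instrument
practice).

Instrument strength is judged by the improvement chi-square -- twice the
log-likelihood gain from adding the instrument to the exposure model --
with values above 10 taken as evidence for a strong instrument.  Below that
the engine refuses to estimate by default, mirroring the decision not to
run MR when the instrument fails the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import NestingError, ValidationError, WeakInstrumentError
from .observational import (
    TIER_COVARIATES,
    Z95,
    RegressionFit,
    fit_linear,
    fit_logistic,
)
from .phenotyping import CONTRAST_CASE_LEVEL, AnalyticCohort, analytic_subset

STRENGTH_THRESHOLD = 10.0
DEFAULT_WEAK_RATIO_GUARD = 2.0  # minimal |beta_gx| / se_gx for a usable ratio


@dataclass(frozen=True)
class InstrumentCheck:
    """Likelihood-ratio diagnostic of instrument relevance."""

    chi2_improvement: float
    strong: bool
    instrument: str
    n: int


@dataclass(frozen=True)
class HeterogeneityResult:
    """Interaction z-test between two log-scale estimates."""

    z: float
    p: float
    estimate_a: tuple  # (log point, SE)
    estimate_b: tuple


@dataclass
class WaldRatioResult:
    """Instrumental-variable estimate with delta-method uncertainty."""

    beta_iv: float
    se_iv: float
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    stage_gx: RegressionFit | None = None
    stage_gy: RegressionFit | None = None
    instrument: str = ""


def instrument_strength(fit_full: RegressionFit, fit_reduced: RegressionFit,
                        instrument: str = "") -> InstrumentCheck:
    """Improvement chi-square: 2 * (loglik_full - loglik_reduced), floored at 0.

    The models must be nested (full = reduced + instrument) and fitted on
    the same rows; under the null of no instrument effect the statistic is
    asymptotically chi-square with 1 degree of freedom.
    """
    if fit_full.n != fit_reduced.n:
        raise NestingError(
            f"fits use different row counts ({fit_full.n} vs {fit_reduced.n})"
        )
    if len(fit_full.terms) <= len(fit_reduced.terms):
        raise NestingError("full model must extend the reduced model")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    return InstrumentCheck(
        chi2_improvement=chi2,
        strong=chi2 > STRENGTH_THRESHOLD,
        instrument=instrument,
        n=fit_full.n,
    )


def wald_ratio(beta_gy: float, se_gy: float, beta_gx: float, se_gx: float,
               weak_ratio_guard: float = DEFAULT_WEAK_RATIO_GUARD) -> WaldRatioResult:
    """Ratio of stage coefficients with the first-order delta-method SE.

    beta_iv = beta_gy / beta_gx;
    se_iv   = sqrt(se_gy^2 / beta_gx^2 + beta_gy^2 * se_gx^2 / beta_gx^4).

    Raises when ``beta_gx`` is zero, or when |beta_gx|/se_gx falls below the
    weak-ratio guard (pass ``weak_ratio_guard=0`` to override).
    """
    if beta_gx == 0:
        raise ValidationError("beta_gx = 0: Wald ratio undefined")
    if se_gy < 0 or se_gx < 0:
        raise ValidationError("standard errors must be nonnegative")
    if weak_ratio_guard > 0 and se_gx > 0 and abs(beta_gx) / se_gx < weak_ratio_guard:
        raise WeakInstrumentError(
            f"|beta_gx|/se_gx = {abs(beta_gx) / se_gx:.2f} below guard "
            f"{weak_ratio_guard}; ratio would be unstable"
        )
    beta_iv = beta_gy / beta_gx
    se_iv = float(np.sqrt(se_gy ** 2 / beta_gx ** 2
                          + beta_gy ** 2 * se_gx ** 2 / beta_gx ** 4))
    z = beta_iv / se_iv if se_iv > 0 else np.inf
    return WaldRatioResult(
        beta_iv=float(beta_iv),
        se_iv=se_iv,
        or_point=float(np.exp(beta_iv)),
        ci_low=float(np.exp(beta_iv - Z95 * se_iv)),
        ci_high=float(np.exp(beta_iv + Z95 * se_iv)),
        p=float(2.0 * st.norm.sf(abs(z))),
    )


def _prepare_subset(cohort: AnalyticCohort, marker: str, contrast: str) -> pd.DataFrame:
    subset = analytic_subset(cohort, marker, contrast)
    df = subset.rows.copy()
    df["at_risk"] = (df[f"{marker}_status"] == "at_risk").astype(float)
    df["case"] = (df["cog_status"] == CONTRAST_CASE_LEVEL[contrast]).astype(float)
    return df


def mr_estimate(cohort: AnalyticCohort, marker: str, contrast: str,
                instrument: str, tier: str = "demographic",
                allow_weak: bool = False) -> WaldRatioResult:
    """Full Wald-type MR estimate on one marker x contrast x tier cell.

    Fits the instrument-exposure and instrument-outcome logistic stages on
    the same complete-case subset and covariate tier, checks instrument
    strength (improvement chi-square > 10 unless ``allow_weak``), and forms
    the ratio.  Both stage fits are attached to the result.
    """
    covs = TIER_COVARIATES[tier]
    df = _prepare_subset(cohort, marker, contrast)
    if df[instrument].std() == 0:
        raise WeakInstrumentError(f"instrument {instrument!r} is constant")
    stage_gx = fit_logistic(df, "at_risk", [instrument] + covs)
    reduced = fit_logistic(df, "at_risk", covs)
    check = instrument_strength(stage_gx, reduced, instrument=instrument)
    if not check.strong and not allow_weak:
        raise WeakInstrumentError(
            f"improvement chi-square {check.chi2_improvement:.2f} <= "
            f"{STRENGTH_THRESHOLD}; refusing MR (pass allow_weak=True to override)"
        )
    stage_gy = fit_logistic(df, "case", [instrument] + covs)
    guard = 0.0 if allow_weak else DEFAULT_WEAK_RATIO_GUARD
    result = wald_ratio(
        stage_gy.coef(instrument), stage_gy.se_of(instrument),
        stage_gx.coef(instrument), stage_gx.se_of(instrument),
        weak_ratio_guard=guard,
    )
    result.stage_gx = stage_gx
    result.stage_gy = stage_gy
    result.instrument = instrument
    return result


def snp_instrument_mode(cohort: AnalyticCohort, marker: str, contrast: str,
                        dosage_term: str = "cetp_dosage",
                        tier: str = "demographic",
                        allow_weak: bool = False) -> WaldRatioResult:
    """MR with a 0/1/2 allele-dosage column replacing the polygenic score."""
    dosage = cohort.rows[dosage_term].dropna().unique()
    if not set(dosage) <= {0, 1, 2}:
        raise ValidationError(f"{dosage_term!r} must take values in {{0, 1, 2}}")
    return mr_estimate(cohort, marker, contrast, dosage_term,
                       tier=tier, allow_weak=allow_weak)


def heterogeneity_test(log_point_a: float, se_a: float,
                       log_point_b: float, se_b: float) -> HeterogeneityResult:
    """Interaction z-test comparing two log-scale estimates.

    z = (b - a) / sqrt(se_a^2 + se_b^2), two-sided normal p.  Used to test
    heterogeneity between the observational and MR estimates.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValidationError("standard errors must be positive")
    z = (log_point_b - log_point_a) / np.sqrt(se_a ** 2 + se_b ** 2)
    return HeterogeneityResult(
        z=float(z),
        p=float(2.0 * st.norm.sf(abs(z))),
        estimate_a=(float(log_point_a), float(se_a)),
        estimate_b=(float(log_point_b), float(se_b)),
    )


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Recover a log-scale SE from a printed ratio-scale confidence interval."""
    if not 0 < ci_low < ci_high:
        raise ValidationError("need 0 < ci_low < ci_high")
    if not 0 < level < 1:
        raise ValidationError("level must lie in (0, 1)")
    z = st.norm.ppf(0.5 + level / 2.0)
    return float((np.log(ci_high) - np.log(ci_low)) / (2.0 * z))


def pleiotropy_screen(cohort: AnalyticCohort, instrument: str,
                      covariates: list) -> pd.DataFrame:
    """Instrument-confounder associations (forest-ready table).

    Each requested covariate is regressed on the instrument (adjusted for
    the five ancestry-specific PCs): linear for continuous covariates,
    logistic for binary ones.  Under a valid instrument every association
    should be null.
    """
    pcs = ["pc1", "pc2", "pc3", "pc4", "pc5"]
    rows = []
    for cov in covariates:
        df = cohort.rows[[cov, instrument] + pcs].dropna()
        vals = df[cov]
        binary = vals.dtype == bool or set(pd.unique(vals)) <= {0, 1, True, False}
        work = df.copy()
        if binary:
            work["_y"] = vals.astype(float)
            fit = fit_logistic(work, "_y", [instrument] + pcs)
            kind = "logistic"
        else:
            work["_y"] = vals.astype(float)
            fit = fit_linear(work, "_y", [instrument] + pcs)
            kind = "linear"
        rows.append({
            "covariate": cov, "model": kind,
            "beta": fit.coef(instrument), "se": fit.se_of(instrument),
            "p": fit.pvalue(instrument), "n": fit.n,
        })
    return pd.DataFrame(rows)


def negative_control(cohort: AnalyticCohort, marker: str,
                     instrument: str | None = None,
                     tier: str = "demographic") -> RegressionFit:
    """Instrument-outcome fit among normal-level, unmedicated participants.

    Restricts to rows with a normal clinical level on ``marker`` and no
    lipid-lowering medication, then fits impaired-vs-normal cognition on the
    marker's polygenic score with the given tier.  With a valid instrument
    the association should be null; the medication covariate is dropped
    from the tier because the subset makes it constant.
    """
    instrument = instrument or f"pgs_{marker}"
    df = cohort.rows
    df = df[(df[f"{marker}_status"] == "normal") & (~df["lipid_med"].astype(bool))]
    df = df.copy()
    df["impaired"] = (df["cog_status"] != "normal").astype(float)
    covs = [c for c in TIER_COVARIATES[tier] if c != "lipid_med"]
    df = df.dropna(subset=[instrument, "impaired"] + covs)
    return fit_logistic(df, "impaired", [instrument] + covs)
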