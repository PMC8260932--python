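"""Descriptive tables and multivariable regression models.

Maximum-likelihood logistic fits go through :mod:`statsmodels` (IRLS via
GLM with a binomial family); linear models use OLS with classical standard
errors.  The closed-form 2x2 odds ratio with the Woolf log-scale SE is kept
as an independent oracle for crude table entries, and the population
attributable fraction is available in both the Miettinen (case-based) and
Levin (population-based) forms because published reports rarely state which
was used.

Covariate tiers mirror the study's adjustment sets:

* ``crude`` -- exposure only;
* ``demographic`` -- age, sex, years of education, lipid-lowering
  medication, cholesterol measurement wave, five ancestry-specific PCs;
* ``health`` -- the demographic set plus ever-drinker, stroke,
  hypertension, diabetes history and BMI.

Categorical covariates use treatment coding with fixed documented
references: sex=male, smoking=never, wave=2006; normal cognition and
normal lipid level are the outcome/exposure references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import (
    ConvergenceError,
    DesignError,
    SeparationError,
    ValidationError,
    ZeroCellError,
)

Z95 = 1.959964  # two-sided 95% normal quantile, fixed for print-faithful CIs

TIER_COVARIATES = {
    "crude": [],
    "demographic": ["age", "sex", "education", "lipid_med", "wave",
                    "pc1", "pc2", "pc3", "pc4", "pc5"],
    "health": ["age", "sex", "education", "lipid_med", "wave",
               "pc1", "pc2", "pc3", "pc4", "pc5",
               "drinker", "stroke", "hypertension", "diabetes", "bmi"],
}

# Treatment-coded expansions; first level listed is the reference.
CATEGORICAL_LEVELS = {
    "sex": ["male", "female"],
    "smoking": ["never", "former", "current"],
    "wave": [2006, 2008, 2010, 2012],
}

MAX_ABS_STANDARDIZED_BETA = 15.0  # separation heuristic on a standardized design


@dataclass
class RegressionFit:
    """One fitted model: coefficients, uncertainty, and likelihood."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    n: int
    converged: bool
    family: str  # "logistic" or "linear"

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def conf_int(self, term: str, z: float = Z95) -> tuple:
        b, s = self.coef(term), self.se_of(term)
        return (b - z * s, b + z * s)

    def pvalue(self, term: str) -> float:
        z = self.coef(term) / self.se_of(term)
        return float(2.0 * st.norm.sf(abs(z)))

    def odds_ratio(self, term: str) -> "OddsRatioResult":
        """Exponentiated coefficient with its 95% Wald interval."""
        if self.family != "logistic":
            raise ValidationError("odds ratios are defined for logistic fits only")
        b, s = self.coef(term), self.se_of(term)
        return OddsRatioResult(
            or_point=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * s)),
            ci_high=float(np.exp(b + Z95 * s)),
            log_or=b,
            se_log_or=s,
        )


@dataclass(frozen=True)
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float


@dataclass(frozen=True)
class PafResult:
    paf: float
    formula: str
    inputs: tuple  # (odds ratio, exposure proportion used)


def build_design(df: pd.DataFrame, covariates: list) -> pd.DataFrame:
    """Intercept-first design matrix with documented treatment coding."""
    cols = {"const": np.ones(len(df))}
    for term in covariates:
        if term in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[term]
            observed = set(df[term].unique())
            unknown = observed - set(levels)
            if unknown:
                raise ValidationError(f"unknown level(s) {unknown} in {term!r}")
            for level in levels[1:]:
                cols[f"{term}[{level}]"] = (df[term] == level).to_numpy(float)
        else:
            vals = df[term].to_numpy()
            if vals.dtype == bool or set(np.unique(vals)) <= {0, 1, True, False}:
                cols[term] = vals.astype(float)
            else:
                cols[term] = vals.astype(float)
    X = pd.DataFrame(cols, index=df.index)
    if np.isnan(X.to_numpy()).any():
        raise ValidationError("missing values in design matrix; subset first")
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise DesignError("design matrix is rank deficient")


def _check_separation(X: pd.DataFrame, beta: np.ndarray) -> None:
    scale = X.to_numpy().std(axis=0)
    scale[scale == 0] = 1.0  # intercept
    if np.any(np.abs(beta * scale) > MAX_ABS_STANDARDIZED_BETA):
        raise SeparationError("diverging coefficient suggests complete separation")


def fit_logistic(df: pd.DataFrame, outcome: str, covariates: list) -> RegressionFit:
    """Maximum-likelihood logistic regression of a binary outcome column.

    ``outcome`` must be 0/1 (or boolean) with both levels present.  Standard
    errors come from the information matrix at the maximum.
    """
    y = df[outcome].to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError(f"outcome {outcome!r} must be binary 0/1")
    if y.min() == y.max():
        raise DesignError(f"outcome {outcome!r} has a single level")
    X = build_design(df, covariates)
    _check_rank(X)
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix: {exc}") from exc
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        if "separation" in str(exc).lower() or "Perfect" in type(exc).__name__:
            raise SeparationError(str(exc)) from exc
        raise
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("Newton iterations did not converge within 100 steps")
    beta = np.asarray(res.params)
    _check_separation(X, beta)
    return RegressionFit(
        terms=list(X.columns),
        beta=beta,
        se=np.asarray(res.bse),
        vcov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        n=len(df),
        converged=True,
        family="logistic",
    )


def fit_linear(df: pd.DataFrame, outcome: str, covariates: list) -> RegressionFit:
    """Least-squares fit with classical SEs and the Gaussian log-likelihood."""
    y = df[outcome].to_numpy(float)
    if np.isnan(y).any():
        raise ValidationError(f"outcome {outcome!r} has missing values; subset first")
    X = build_design(df, covariates)
    _check_rank(X)
    if len(df) <= X.shape[1]:
        raise DesignError("need more rows than model terms")
    res = sm.OLS(y, X).fit()
    return RegressionFit(
        terms=list(X.columns),
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        vcov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        n=len(df),
        converged=True,
        family="linear",
    )


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Closed-form cross-product odds ratio with the Woolf SE.

    Cell layout: ``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed
    controls, ``d`` unexposed controls; OR = (a*d)/(b*c),
    SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d).  Zero cells raise (no
    continuity correction).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValidationError("counts must be nonnegative")
    if any(x == 0 for x in cells):
        raise ZeroCellError("zero cell in 2x2 table")
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return OddsRatioResult(
        or_point=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        log_or=log_or,
        se_log_or=se,
    )


def expand_2x2(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Expand 2x2 counts into individual rows with `case` and `exposed` columns."""
    rows = (
        [(1, 1)] * int(a) + [(1, 0)] * int(b) + [(0, 1)] * int(c) + [(0, 0)] * int(d)
    )
    return pd.DataFrame(rows, columns=["case", "exposed"])


def tc_hdl_ratio_term(tc: float, hdl: float) -> float:
    """Natural log of the TC/HDL-C ratio, a continuous atherogenic exposure."""
    if tc is None or hdl is None or tc <= 0 or hdl <= 0:
        raise ValidationError("tc and hdl must both be positive")
    return float(np.log(tc / hdl))


def paf(or_point: float, p_exposed: float, formula: str = "miettinen") -> PafResult:
    """Population attributable fraction from an odds ratio.

    ``miettinen`` uses the exposure proportion *among cases*:
    PAF = p_c * (OR - 1) / OR.  ``levin`` uses the population proportion:
    PAF = p * (OR - 1) / (1 + p * (OR - 1)).  Both treat the OR as a risk
    ratio, appropriate for rare outcomes.
    """
    if or_point <= 0:
        raise ValidationError("odds ratio must be positive")
    if not 0 <= p_exposed <= 1:
        raise ValidationError("exposure proportion must lie in [0, 1]")
    if formula == "miettinen":
        value = p_exposed * (or_point - 1.0) / or_point
    elif formula == "levin":
        excess = p_exposed * (or_point - 1.0)
        value = excess / (1.0 + excess)
    else:
        raise ValidationError(f"unknown PAF formula {formula!r}")
    return PafResult(paf=float(value), formula=formula, inputs=(or_point, p_exposed))


def bivariate_table(df: pd.DataFrame, group: str, variables: list) -> pd.DataFrame:
    """Descriptive comparison of ``variables`` across levels of ``group``.

    Categorical variables get per-level counts (frequencies) and a Pearson
    chi-square p (no continuity correction); continuous variables get
    mean (SD) per group and a one-way ANOVA p.  Each variable uses its own
    non-missing rows.
    """
    levels = [lv for lv in df[group].dropna().unique()]
    if len(levels) < 2:
        raise DesignError(f"group {group!r} has fewer than 2 levels")
    records = []
    for var in variables:
        sub = df[[group, var]].dropna()
        vals = sub[var]
        is_categorical = (
            vals.dtype == object or vals.dtype == bool
            or var in CATEGORICAL_LEVELS
            or vals.nunique() <= 2
        )
        if is_categorical:
            table = pd.crosstab(sub[var], sub[group])
            if table.shape[0] < 2:
                p = np.nan
            else:
                chi2, p, _, _ = st.chi2_contingency(table.to_numpy(), correction=False)
            for level_name, row in table.iterrows():
                total = row.sum()
                records.append({
                    "variable": var, "level": level_name, "kind": "categorical",
                    "summary": " / ".join(
                        f"{row[g]} ({row[g] / table[g].sum():.1%})" for g in table.columns
                    ),
                    "n": int(total), "p": float(p),
                })
        else:
            groups = [g[var].to_numpy(float) for _, g in sub.groupby(group)]
            _, p = st.f_oneway(*groups)
            records.append({
                "variable": var, "level": "", "kind": "continuous",
                "summary": " / ".join(
                    f"{g.mean():.2f} ({g.std(ddof=1):.2f})" for g in groups
                ),
                "n": int(len(sub)), "p": float(p),
            })
    return pd.DataFrame.from_records(records)
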