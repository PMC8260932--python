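"""Synthetic cohort generator for the lipid-cognition pipeline.

Generates participant-level cohorts with the statistical structure the
analysis assumes, so every stage (phenotyping, observational models,
instrumental-variable estimation) is testable without restricted data:

* standardized polygenic scores (mean 0, SD 1), independent of all
  confounders by construction -- the IV independence assumption holds
  exactly unless the pleiotropy knob is turned;
* sex-specific Gaussian lipid latents calibrated so the clinical
  dichotomization yields roughly 32% at-risk HDL-C and 16% at-risk TC;
* a three-level cognitive status (~86/12/2% normal/CIND/dementia) drawn
  from a baseline-category multinomial logit, so that conditioning on the
  two levels of a contrast yields an exactly correctly-specified logistic
  model;
* Langa-Weir component scores drawn uniformly over the integer
  compositions of a total sampled within the status band, so the scorer
  never errors on generated rows.

Structural effect convention: the causal knobs ``theta_cind`` and
``theta_dementia`` multiply the *at-risk liability* -- the true log-odds of
at-risk clinical status given genes, sex, and confounders -- rather than
the observed binary snapshot.  The liability is the long-run (lifetime)
exposure burden that a polygenic instrument proxies, and it is the
exposure contrast for which the two-stage logistic Wald ratio is a
consistent estimator; driving the outcome by the binary snapshot instead
would build in a structural attenuation that no ratio estimator removes.

Randomness uses one master seed split into named sub-streams, so toggling
one knob (e.g. the causal effect) leaves all other draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import ParseError, ValidationError
from .phenotyping import (
    HDL_CUTOFF_FEMALE,
    HDL_CUTOFF_MALE,
    REQUIRED_COLUMNS,
    STATUS_BANDS,
    TC_CUTOFF,
)

# (effect on latent HDL-C, mg/dL; effect on outcome log-odds).
# Age, education, and BMI are centered at 68 y, 13.2 y, 28.4 kg/m^2;
# "smoking" applies to current smokers; "drinking" to ever-drinkers.
DEFAULT_CONFOUNDER_EFFECTS = {
    "age": (0.0, 0.05),
    "education": (0.0, -0.22),
    "bmi": (-0.35, -0.02),
    "smoking": (-4.0, 0.20),
    "diabetes": (-4.0, 0.30),
    "hypertension": (-2.5, 0.20),
    "stroke": (-2.0, 1.00),
    "drinking": (2.0, -0.50),
}

_CENTER = {"age": 68.0, "education": 13.2, "bmi": 28.4}


@dataclass
class SyntheticParams:
    """All structural coefficients, prevalence targets, and knobs.

    Defaults are calibrated to the European-ancestry marginals: at-risk
    fractions, status split, lipid means/SDs, and instrument-exposure
    strength (log-OR about -0.25 per SD of the HDL score, improvement
    chi-square near 100 at n ~ 8,000).
    """

    n: int = 10_000
    seed: int = 0
    # instrument -> latent lipid, mg/dL per SD of the polygenic score
    gamma_hdl: float = 2.3
    gamma_tc: float = 4.6
    hdl_mean_male: float = 50.0
    hdl_mean_female: float = 59.0
    hdl_sd: float = 15.5
    tc_mean_male: float = 192.0
    tc_mean_female: float = 201.0
    tc_sd: float = 41.0
    # structural log-odds ratios of the at-risk liability on each contrast
    theta_cind: float = 0.0
    theta_dementia: float = 0.0
    outcome_marker: str = "hdl"
    # direct instrument -> outcome log-odds per SD (0 = valid instrument)
    pleiotropy_delta: float = 0.0
    confounder_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS))
    target_prevalence: dict = field(
        default_factory=lambda: {"normal": 0.858, "cind": 0.121, "dementia": 0.021})
    wave_probs: dict = field(
        default_factory=lambda: {2006: 0.387, 2008: 0.380, 2010: 0.121, 2012: 0.112})
    female_frac: float = 0.581
    reversal_rate: float = 0.0027
    proxy_rate: float = 0.0
    hdl_missing_rate: float = 0.104
    tc_missing_rate: float = 0.001
    vocab_missing_rate: float = 0.65
    cetp_allele_freq: float = 0.32
    cetp_beta_hdl: float = 1.5  # mg/dL of HDL-C per risk allele
    pgs_cog_beta: float = -0.12  # cognition score protects against impairment
    apoe4_frac: float = 0.258
    apoe4_beta_dementia: float = 0.35

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.hdl_sd <= 0 or self.tc_sd <= 0:
            raise ValidationError("lipid SDs must be positive")
        if self.outcome_marker not in ("hdl", "tc"):
            raise ValidationError("outcome_marker must be 'hdl' or 'tc'")
        for name, probs in [("target_prevalence", self.target_prevalence),
                            ("wave_probs", self.wave_probs)]:
            vals = np.array(list(probs.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1) or abs(vals.sum() - 1.0) > 1e-6:
                raise ValidationError(f"{name} must be probabilities summing to 1")
        for rate_name in ("female_frac", "reversal_rate", "proxy_rate",
                          "hdl_missing_rate", "tc_missing_rate",
                          "vocab_missing_rate", "cetp_allele_freq", "apoe4_frac"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{rate_name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Langa-Weir component compositions

_CAPS = (10, 10, 5, 2)  # imm_recall, del_recall, serial7, backward20


def _composition_tables():
    """Suffix composition counts W[j][t]: ways to write t with parts j..end."""
    tables = [np.ones(_CAPS[-1] + 1)]
    for cap in reversed(_CAPS[:-1]):
        prev = tables[0]
        tables.insert(0, np.convolve(np.ones(cap + 1), prev))
    return tables  # tables[0] covers totals 0..27


_W = _composition_tables()


def _sample_stage(remaining: np.ndarray, cap: int, w_next: np.ndarray,
                  u: np.ndarray) -> np.ndarray:
    """Draw one component k with P(k) proportional to w_next[remaining - k]."""
    max_total = cap + len(w_next) - 1
    M = np.zeros((max_total + 1, cap + 1))
    for k in range(cap + 1):
        t = np.arange(max_total + 1) - k
        valid = (t >= 0) & (t < len(w_next))
        M[valid, k] = w_next[t[valid]]
    cdf = np.cumsum(M, axis=1)
    cdf = cdf / cdf[:, -1:]
    return (u[:, None] > cdf[remaining]).sum(axis=1)


def sample_components(totals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over integer compositions of each total into the four
    Langa-Weir components (caps 10/10/5/2).  Returns an (n, 4) array."""
    totals = np.asarray(totals, dtype=int)
    if np.any((totals < 0) | (totals > sum(_CAPS))):
        raise ValidationError("totals must lie in [0, 27]")
    n = len(totals)
    out = np.zeros((n, 4), dtype=int)
    remaining = totals.copy()
    for j, cap in enumerate(_CAPS[:-1]):
        k = _sample_stage(remaining, cap, _W[j + 1], rng.random(n))
        out[:, j] = k
        remaining = remaining - k
    out[:, 3] = remaining
    return out


# ---------------------------------------------------------------------------
# Cohort generation


def _at_risk_liability(marker: str, predictor: np.ndarray, sd: float,
                       sex_is_female: np.ndarray) -> np.ndarray:
    """Log-odds of at-risk clinical status given the noise-free predictor."""
    if marker == "hdl":
        cut = np.where(sex_is_female, HDL_CUTOFF_FEMALE, HDL_CUTOFF_MALE)
        z = (cut - predictor) / sd
    else:
        z = (predictor - TC_CUTOFF) / sd
    return st.norm.logcdf(z) - st.norm.logsf(z)


def _calibrate_intercepts(eta_c: np.ndarray, eta_d: np.ndarray,
                          targets: dict) -> tuple:
    """Solve baseline-category intercepts so sample-mean class probabilities
    hit the target prevalences (fixed-point on the log scale)."""
    t_n, t_c, t_d = targets["normal"], targets["cind"], targets["dementia"]
    a_c = np.log(t_c / t_n)
    a_d = np.log(t_d / t_n)
    for _ in range(200):
        ec = np.exp(a_c + eta_c)
        ed = np.exp(a_d + eta_d)
        denom = 1.0 + ec + ed
        pc = float((ec / denom).mean())
        pdem = float((ed / denom).mean())
        step_c = np.log(t_c / pc)
        step_d = np.log(t_d / pdem)
        a_c += step_c
        a_d += step_d
        if abs(step_c) < 1e-10 and abs(step_d) < 1e-10:
            break
    return a_c, a_d


def simulate_cohort(params: SyntheticParams) -> pd.DataFrame:
    """Generate one cohort as a raw participant table (deterministic in seed).

    Generation order: demographics and confounders; standardized polygenic
    scores and the CETP dosage (independent of confounders); lipid latents
    and clinical measurements; cognitive status from the multinomial
    outcome model; component scores within the status band; waves, PCs,
    missingness and exclusion flags.
    """
    params.validate()
    n = params.n
    master = np.random.SeedSequence(params.seed)
    names = ["demo", "genetics", "hdl_noise", "tc_noise", "outcome",
             "components", "admin"]
    rng = {name: np.random.default_rng(child)
           for name, child in zip(names, master.spawn(len(names)))}

    # (1) demographics and confounders
    demo = rng["demo"]
    female = demo.random(n) < params.female_frac
    sex = np.where(female, "female", "male")
    age = demo.integers(50, 91, size=n)
    education = np.clip(np.round(demo.normal(13.2, 2.5, n)), 0, 17).astype(int)
    bmi = np.clip(demo.normal(28.4, 5.8, n), 15.0, 55.0)
    smoking = demo.choice(["never", "former", "current"], size=n,
                          p=[0.423, 0.452, 0.125])
    drinker = demo.random(n) < 0.568
    stroke = demo.random(n) < 0.070
    hypertension = demo.random(n) < 0.613
    diabetes = demo.random(n) < 0.198
    lipid_med = demo.random(n) < 0.503
    apoe4 = demo.random(n) < params.apoe4_frac

    confounders = {
        "age": age - _CENTER["age"],
        "education": education - _CENTER["education"],
        "bmi": bmi - _CENTER["bmi"],
        "smoking": (smoking == "current").astype(float),
        "diabetes": diabetes.astype(float),
        "hypertension": hypertension.astype(float),
        "stroke": stroke.astype(float),
        "drinking": drinker.astype(float),
    }

    # (2) instruments: standardized scores, independent of confounders
    gen = rng["genetics"]
    pgs_hdl = gen.standard_normal(n)
    pgs_tc = gen.standard_normal(n)
    pgs_cog = gen.standard_normal(n)
    cetp = gen.binomial(2, params.cetp_allele_freq, n)

    # (3) latent lipids: sex mean + instrument + confounders + noise
    lipid_shift = np.zeros(n)
    for name, (on_lipid, _) in params.confounder_effects.items():
        lipid_shift += on_lipid * confounders[name]
    hdl_pred = (np.where(female, params.hdl_mean_female, params.hdl_mean_male)
                + params.gamma_hdl * pgs_hdl
                + params.cetp_beta_hdl * (cetp - 2 * params.cetp_allele_freq)
                + lipid_shift)
    hdl = np.clip(hdl_pred + params.hdl_sd * rng["hdl_noise"].standard_normal(n),
                  5.0, None)
    tc_pred = (np.where(female, params.tc_mean_female, params.tc_mean_male)
               + params.gamma_tc * pgs_tc)
    tc = np.clip(tc_pred + params.tc_sd * rng["tc_noise"].standard_normal(n),
                 60.0, None)

    # (4)/(5) outcome: baseline-category multinomial on the at-risk liability
    if params.outcome_marker == "hdl":
        liability = _at_risk_liability("hdl", hdl_pred, params.hdl_sd, female)
        pgs_marker = pgs_hdl
    else:
        liability = _at_risk_liability("tc", tc_pred, params.tc_sd, female)
        pgs_marker = pgs_tc
    outcome_shift = np.zeros(n)
    for name, (_, on_outcome) in params.confounder_effects.items():
        outcome_shift += on_outcome * confounders[name]
    outcome_shift += params.pgs_cog_beta * pgs_cog
    outcome_shift += params.pleiotropy_delta * pgs_marker
    eta_c = params.theta_cind * liability + outcome_shift
    eta_d = (params.theta_dementia * liability + outcome_shift
             + params.apoe4_beta_dementia * apoe4.astype(float))
    a_c, a_d = _calibrate_intercepts(eta_c, eta_d, params.target_prevalence)
    ec = np.exp(a_c + eta_c)
    ed = np.exp(a_d + eta_d)
    denom = 1.0 + ec + ed
    u = rng["outcome"].random(n)
    status = np.full(n, "normal", dtype=object)
    status[u < (ec + ed) / denom] = "cind"
    status[u < ed / denom] = "dementia"

    # (6) component scores uniform within the status band
    comp_rng = rng["components"]
    lo = np.array([STATUS_BANDS[s][0] for s in status])
    hi = np.array([STATUS_BANDS[s][1] for s in status])
    totals = lo + np.floor(comp_rng.random(n) * (hi - lo + 1)).astype(int)
    comps = sample_components(totals, comp_rng)
    vocab = np.clip(np.round(comp_rng.normal(5.9, 1.9, n)), 0, 10).astype(int)

    # (8) administrative: waves, PCs, flags, missingness
    admin = rng["admin"]
    waves = np.array(list(params.wave_probs))
    wave = admin.choice(waves, size=n, p=list(params.wave_probs.values()))
    pcs = admin.standard_normal((n, 5))
    reversal = admin.random(n) < params.reversal_rate
    proxy = admin.random(n) < params.proxy_rate
    hdl_obs = np.where(admin.random(n) < params.hdl_missing_rate, np.nan, hdl)
    tc_obs = np.where(admin.random(n) < params.tc_missing_rate, np.nan, tc)
    vocab_obs = pd.array(vocab, dtype="Int64")
    vocab_obs[admin.random(n) < params.vocab_missing_rate] = pd.NA

    df = pd.DataFrame({
        "id": [f"S{i:06d}" for i in range(n)],
        "age": age.astype(float),
        "sex": sex,
        "education": education,
        "wave": wave.astype(int),
        "hdl": hdl_obs,
        "tc": tc_obs,
        "lipid_med": lipid_med,
        "stroke": stroke,
        "hypertension": hypertension,
        "diabetes": diabetes,
        "smoking": smoking,
        "drinker": drinker,
        "bmi": bmi,
        "pgs_hdl": pgs_hdl,
        "pgs_tc": pgs_tc,
        "pgs_cog": pgs_cog,
        "apoe4": apoe4,
        "cetp_dosage": cetp,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2],
        "pc4": pcs[:, 3], "pc5": pcs[:, 4],
        "imm_recall": comps[:, 0],
        "del_recall": comps[:, 1],
        "serial7": comps[:, 2],
        "backward20": comps[:, 3],
        "vocab": vocab_obs,
        "prior_dementia_then_normal": reversal,
        "proxy": proxy,
    })
    return df[REQUIRED_COLUMNS]


SCENARIO_NOTES = {
    "valid_iv_effect": (
        "Causal at-risk HDL-C liability effect on dementia (log-OR ln 2.15), "
        "no pleiotropy, moderate confounding.  Expect: MR recovers the "
        "structural log-OR with nominal CI coverage; the observational "
        "estimate is attenuated/confounded; the dementia MR cell is "
        "significant in most replicates."
    ),
    "valid_iv_null": (
        "No causal effect, no pleiotropy, moderate confounding.  Expect: "
        "MR CI covers zero at the nominal rate."
    ),
    "confounded_null": (
        "No causal effect, strong shared confounding of lipids and "
        "cognition.  Expect: the observational exposure OR is detectably "
        "biased away from 1 while the MR CI still covers zero."
    ),
    "pleiotropic": (
        "Direct instrument->outcome path (delta = 0.3 log-odds per SD), no "
        "causal lipid effect.  Expect: the negative-control analysis "
        "detects a nonzero instrument-outcome association and MR is biased."
    ),
    "weak_instrument": (
        "Instrument nearly unrelated to the lipid (gamma ~ 0).  Expect: the "
        "improvement chi-square falls below 10 and the engine refuses MR; "
        "observational cells still run."
    ),
}


def default_scenarios(n: int = 10_000, seed: int = 0) -> dict:
    """Named parameter sets covering the qualitative regimes the pipeline
    must distinguish (see :data:`SCENARIO_NOTES`)."""
    base = SyntheticParams(n=n, seed=seed)
    strong = {name: (2.5 * lip, 2.5 * out)
              for name, (lip, out) in DEFAULT_CONFOUNDER_EFFECTS.items()}
    return {
        "valid_iv_effect": replace(base, theta_dementia=float(np.log(2.15))),
        "valid_iv_null": replace(base),
        "confounded_null": replace(base, confounder_effects=strong),
        "pleiotropic": replace(base, pleiotropy_delta=0.3),
        "weak_instrument": replace(base, gamma_hdl=0.05, gamma_tc=0.05,
                                   cetp_beta_hdl=0.0),
    }


# ---------------------------------------------------------------------------
# Delimited-text round trip

_BOOL_COLUMNS = ["lipid_med", "stroke", "hypertension", "diabetes", "drinker",
                 "apoe4", "prior_dementia_then_normal", "proxy"]
_INT_COLUMNS = ["education", "wave", "cetp_dosage",
                "imm_recall", "del_recall", "serial7", "backward20"]
_FLOAT_COLUMNS = ["age", "hdl", "tc", "bmi", "pgs_hdl", "pgs_tc", "pgs_cog",
                  "pc1", "pc2", "pc3", "pc4", "pc5"]
_STR_COLUMNS = ["id", "sex", "smoking"]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort as comma-separated text (UTF-8, '.' decimal, empty
    field = missing).  Booleans are stored as 0/1."""
    out = df.copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def read_cohort(path, rename: dict | None = None) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort` (lossless round trip).

    ``rename`` maps file column names to the canonical names.  Raises
    :class:`ParseError` naming the missing column or the offending line.
    """
    dtypes = {c: "float64" for c in _FLOAT_COLUMNS}
    dtypes.update({c: "int64" for c in _INT_COLUMNS})
    dtypes.update({c: "Int64" for c in _BOOL_COLUMNS})
    dtypes.update({c: "string" for c in _STR_COLUMNS})
    dtypes["vocab"] = "Int64"
    try:
        raw = pd.read_csv(path, dtype="object")
    except pd.errors.ParserError as exc:  # malformed rows carry line numbers
        raise ParseError(str(exc)) from exc
    if rename:
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    df = pd.DataFrame(index=raw.index)
    for col in REQUIRED_COLUMNS:
        try:
            if dtypes[col] == "string":
                df[col] = raw[col].astype("string")
            else:
                df[col] = pd.to_numeric(raw[col]).astype(dtypes[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"column {col!r}: {exc}") from exc
    for col in _BOOL_COLUMNS:
        if df[col].isna().any():
            raise ParseError(f"column {col!r} has missing boolean values")
        df[col] = df[col].astype(bool)
    for col in _STR_COLUMNS:
        df[col] = df[col].astype(object)
    return df
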