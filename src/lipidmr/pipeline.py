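"""Study orchestration: simulate/ingest -> phenotype -> models -> reports.

`run_study` executes the full flow for a configured set of markers,
contrasts and adjustment tiers, writing delimited report tables that
mirror the published layouts:

* instrument strength (instrument->exposure OR with the improvement
  chi-square),
* polygenic score -> outcome (total effect, and the direct effect
  additionally adjusted for the clinical lipid level),
* main results (observational logistic OR, Wald-type MR OR, P for
  heterogeneity),
* cognitive-domain results (linear and instrumental-variable estimates).

Any cell that fails (weak instrument, separation, degenerate subset) is
logged and marked unavailable; the remaining cells still run.  Reports are
byte-identical across reruns with the same config and seed, so log lines
carry a step counter rather than wall-clock timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LipidMRError, ValidationError
from .mr import (
    heterogeneity_test,
    instrument_strength,
    mr_estimate,
    se_from_ci,
    wald_ratio,
)
from .observational import TIER_COVARIATES, fit_linear, fit_logistic
from .phenotyping import (
    CONTRAST_CASE_LEVEL,
    MODEL_COVARIATES,
    AnalyticCohort,
    analytic_subset,
    apply_exclusions,
    phenotype_cohort,
)
from .simulate import default_scenarios, read_cohort, simulate_cohort

DOMAIN_SCORES = ["imm_recall", "del_recall", "serial7", "backward20", "vocab"]


@dataclass
class RunConfig:
    """Everything a reproducible study run needs."""

    scenario: str | None = "valid_iv_effect"
    input_path: str | None = None
    ancestry: str = "european"
    tiers: list = field(default_factory=lambda: ["crude", "demographic", "health"])
    markers: list = field(default_factory=lambda: ["hdl", "tc"])
    contrasts: list = field(
        default_factory=lambda: ["cind_vs_normal", "dementia_vs_normal"])
    instruments: dict = field(
        default_factory=lambda: {"hdl": "pgs_hdl", "tc": "pgs_tc"})
    outdir: str = "lipidmr_run"
    seed: int = 0
    n: int = 10_000
    rounding: int = 2
    column_map: dict | None = None

    def validate(self) -> None:
        bad = [t for t in self.tiers if t not in TIER_COVARIATES]
        if bad:
            raise ValidationError(f"unknown adjustment tier(s): {bad}")
        if self.scenario is None and self.input_path is None:
            raise ValidationError("need either a scenario name or an input path")


def format_p(p: float) -> str:
    """Print-faithful heterogeneity p: two decimals, three when a value
    below 0.05 would otherwise round up to the boundary."""
    if np.isnan(p):
        return ""
    if p < 0.0005:
        return "<0.001"
    if p < 0.05 and round(p, 2) >= 0.05:
        return f"{p:.3f}"
    return f"{p:.2f}"


def audit_printed_table(rows, decimals: int = 2) -> pd.DataFrame:
    """Re-derive a heterogeneity column from printed (OR, CI) pairs alone.

    ``rows`` is an iterable of (label, or_a, (lo_a, hi_a), or_b, (lo_b, hi_b));
    log-scale SEs are recovered from the CIs and the interaction z-test is
    applied.  Returns the per-row p, both raw and rounded to ``decimals``.
    """
    records = []
    for label, or_a, ci_a, or_b, ci_b in rows:
        for name, (lo, hi) in (("a", ci_a), ("b", ci_b)):
            if not 0 < lo < hi:
                raise ValidationError(f"row {label!r}: inverted CI for {name}")
        het = heterogeneity_test(np.log(or_a), se_from_ci(*ci_a),
                                 np.log(or_b), se_from_ci(*ci_b))
        records.append({
            "label": label, "z": het.z, "p": het.p,
            "p_rounded": round(het.p, decimals),
            "p_printed": format_p(het.p),
        })
    return pd.DataFrame.from_records(records)


def _load_cohort(config: RunConfig, log: list) -> pd.DataFrame:
    if config.input_path is not None:
        log.append(f"ingest: reading cohort from {config.input_path}")
        return read_cohort(config.input_path, rename=config.column_map)
    scenarios = default_scenarios(n=config.n, seed=config.seed)
    if config.scenario not in scenarios:
        raise ValidationError(
            f"unknown scenario {config.scenario!r}; "
            f"choose from {sorted(scenarios)}")
    log.append(f"simulate: scenario={config.scenario} n={config.n} "
               f"seed={config.seed}")
    return simulate_cohort(scenarios[config.scenario])


def _round(x: float, k: int) -> float:
    return float(np.round(x, k))


def run_study(config: RunConfig) -> dict:
    """Run the full study flow; returns the report tables and writes them
    (plus a run log) under ``config.outdir``."""
    config.validate()
    log: list[str] = []
    raw = _load_cohort(config, log)
    pheno = phenotype_cohort(raw)
    cohort = apply_exclusions(pheno)
    log.append(f"exclusions: {cohort.exclusion_log} -> retained n={cohort.n}")

    k = config.rounding
    strength_rows, pgs_rows, main_rows, domain_rows = [], [], [], []

    for marker in config.markers:
        instrument = config.instruments[marker]
        for contrast in config.contrasts:
            try:
                subset = analytic_subset(cohort, marker, contrast)
            except LipidMRError as exc:
                log.append(f"subset {marker}/{contrast}: SKIPPED ({exc})")
                continue
            df = subset.rows.copy()
            df["at_risk"] = (df[f"{marker}_status"] == "at_risk").astype(float)
            df["case"] = (df["cog_status"] == CONTRAST_CASE_LEVEL[contrast]).astype(float)
            log.append(f"subset {subset.subset_label} ({marker}/{contrast}): "
                       f"n={subset.n}")
            for tier in config.tiers:
                covs = TIER_COVARIATES[tier]
                cell = f"{marker}/{contrast}/{tier}"
                # instrument -> exposure stage and strength
                try:
                    full = fit_logistic(df, "at_risk", [instrument] + covs)
                    reduced = fit_logistic(df, "at_risk", covs)
                    check = instrument_strength(full, reduced, instrument)
                    orr = full.odds_ratio(instrument)
                    strength_rows.append({
                        "marker": marker, "contrast": contrast, "tier": tier,
                        "n": full.n, "or": _round(orr.or_point, k),
                        "ci_low": _round(orr.ci_low, k),
                        "ci_high": _round(orr.ci_high, k),
                        "improvement_chi2": _round(check.chi2_improvement, 1),
                        "strong": check.strong,
                    })
                    weak = not check.strong
                except LipidMRError as exc:
                    log.append(f"strength {cell}: FAILED ({exc})")
                    weak = True

                # polygenic score -> outcome (total and direct effects)
                for effect, extra in (("total", []), ("direct", ["at_risk"])):
                    try:
                        fit = fit_logistic(df, "case", [instrument] + extra + covs)
                        orr = fit.odds_ratio(instrument)
                        pgs_rows.append({
                            "marker": marker, "contrast": contrast, "tier": tier,
                            "effect": effect, "n": fit.n,
                            "or": _round(orr.or_point, k),
                            "ci_low": _round(orr.ci_low, k),
                            "ci_high": _round(orr.ci_high, k),
                        })
                    except LipidMRError as exc:
                        log.append(f"pgs-outcome {cell} ({effect}): FAILED ({exc})")

                # observational OR, Wald-type MR OR, heterogeneity
                row = {"marker": marker, "contrast": contrast, "tier": tier,
                       "n": len(df)}
                try:
                    obs = fit_logistic(df, "case", ["at_risk"] + covs)
                    obs_or = obs.odds_ratio("at_risk")
                    row.update(or_obs=_round(obs_or.or_point, k),
                               obs_ci_low=_round(obs_or.ci_low, k),
                               obs_ci_high=_round(obs_or.ci_high, k))
                except LipidMRError as exc:
                    log.append(f"observational {cell}: FAILED ({exc})")
                    obs_or = None
                if weak:
                    log.append(f"mr {cell}: SKIPPED (weak instrument; no MR "
                               f"performed for this ancestry/cell)")
                    mr = None
                else:
                    try:
                        mr = mr_estimate(cohort, marker, contrast, instrument,
                                         tier=tier)
                        row.update(or_mr=_round(mr.or_point, k),
                                   mr_ci_low=_round(mr.ci_low, k),
                                   mr_ci_high=_round(mr.ci_high, k))
                    except LipidMRError as exc:
                        log.append(f"mr {cell}: FAILED ({exc})")
                        mr = None
                if obs_or is not None and mr is not None:
                    het = heterogeneity_test(obs_or.log_or, obs_or.se_log_or,
                                             mr.beta_iv, mr.se_iv)
                    row["het_p"] = format_p(het.p)
                main_rows.append(row)

            # cognitive-domain linear and IV estimates (crude + demographic)
            if contrast == config.contrasts[0]:
                domain_rows.extend(
                    _domain_cells(cohort, marker, instrument, config, log))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "instrument_strength": pd.DataFrame(strength_rows),
        "pgs_outcome": pd.DataFrame(pgs_rows),
        "main_results": pd.DataFrame(main_rows),
        "domain_results": pd.DataFrame(domain_rows),
    }
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    log_text = "\n".join(f"[{i:03d}] {line}" for i, line in enumerate(log)) + "\n"
    (outdir / "run.log").write_text(log_text)
    tables["log"] = log
    tables["cohort"] = cohort
    return tables


def _domain_cells(cohort: AnalyticCohort, marker: str, instrument: str,
                  config: RunConfig, log: list) -> list:
    """Linear and Wald-type IV estimates for each cognitive-domain score."""
    k = config.rounding
    rows = []
    base = cohort.rows
    tiers = [t for t in config.tiers if t in ("crude", "demographic")]
    for domain in DOMAIN_SCORES:
        df = base[base[f"{marker}_status"].notna()].copy()
        df["at_risk"] = (df[f"{marker}_status"] == "at_risk").astype(float)
        df["_score"] = df[domain].astype(float)
        df = df.dropna(subset=["_score"] + MODEL_COVARIATES)
        for tier in tiers:
            covs = TIER_COVARIATES[tier]
            cell = f"domain {marker}/{domain}/{tier}"
            try:
                lin = fit_linear(df, "_score", ["at_risk"] + covs)
                gx = fit_logistic(df, "at_risk", [instrument] + covs)
                gy = fit_linear(df, "_score", [instrument] + covs)
                iv = wald_ratio(gy.coef(instrument), gy.se_of(instrument),
                                gx.coef(instrument), gx.se_of(instrument))
                lo, hi = lin.conf_int("at_risk")
                het = heterogeneity_test(lin.coef("at_risk"),
                                         lin.se_of("at_risk"),
                                         iv.beta_iv, iv.se_iv)
                rows.append({
                    "marker": marker, "domain": domain, "tier": tier,
                    "n": lin.n,
                    "beta": _round(lin.coef("at_risk"), k),
                    "ci_low": _round(lo, k), "ci_high": _round(hi, k),
                    "beta_iv": _round(iv.beta_iv, k),
                    "iv_ci_low": _round(iv.beta_iv - 1.959964 * iv.se_iv, k),
                    "iv_ci_high": _round(iv.beta_iv + 1.959964 * iv.se_iv, k),
                    "het_p": format_p(het.p),
                })
            except LipidMRError as exc:
                log.append(f"{cell}: FAILED ({exc})")
    return rows
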