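"""Synthetic cohort generator: determinism, calibration, file round trips."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import lipidmr as lm
from lipidmr.errors import ParseError, ValidationError
from lipidmr.phenotyping import COMPONENT_RANGES
from lipidmr.published import CALIBRATION_ANCHORS
from lipidmr.simulate import (
    SyntheticParams,
    default_scenarios,
    read_cohort,
    sample_components,
    simulate_cohort,
    write_cohort,
)


def test_same_seed_is_byte_identical(tmp_path):
    params = SyntheticParams(n=500, seed=42)
    a, b = simulate_cohort(params), simulate_cohort(params)
    pd.testing.assert_frame_equal(a, b)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(a, pa)
    write_cohort(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_substreams_isolate_knobs():
    """Toggling the causal effect reuses every non-outcome draw, so the
    lipid and genetic columns are unchanged."""
    base = simulate_cohort(SyntheticParams(n=400, seed=8))
    bumped = simulate_cohort(SyntheticParams(n=400, seed=8, theta_dementia=1.0))
    for col in ["hdl", "tc", "pgs_hdl", "pgs_tc", "age", "sex", "bmi"]:
        pd.testing.assert_series_equal(base[col], bumped[col])
    # the outcome distribution itself must respond to the knob
    assert not base[["imm_recall", "del_recall"]].equals(
        bumped[["imm_recall", "del_recall"]])


def test_marginal_calibration_anchors():
    """Default scenario reproduces the published marginal fractions within
    two percentage points at n=10,000."""
    df = lm.phenotype_cohort(simulate_cohort(SyntheticParams(n=10_000, seed=123)))
    at_risk_hdl = (df["hdl_status"] == "at_risk").sum() / df["hdl_status"].notna().sum()
    at_risk_tc = (df["tc_status"] == "at_risk").sum() / df["tc_status"].notna().sum()
    status = df["cog_status"].value_counts(normalize=True)
    assert abs(at_risk_hdl - CALIBRATION_ANCHORS["at_risk_hdl"]) < 0.02
    assert abs(at_risk_tc - CALIBRATION_ANCHORS["at_risk_tc"]) < 0.02
    assert abs(status["normal"] - CALIBRATION_ANCHORS["status_normal"]) < 0.02
    assert abs(status["cind"] - CALIBRATION_ANCHORS["status_cind"]) < 0.02
    assert abs(status["dementia"] - CALIBRATION_ANCHORS["status_dementia"]) < 0.02


def test_components_always_scoreable():
    df = simulate_cohort(SyntheticParams(n=2_000, seed=5))
    for name in ["imm_recall", "del_recall", "serial7", "backward20"]:
        lo, hi = COMPONENT_RANGES[name]
        assert df[name].between(lo, hi).all()
    # the scorer never errors on generated rows
    for row in df.itertuples():
        lm.score_langa_weir(row.imm_recall, row.del_recall, row.serial7,
                            row.backward20)


def test_composition_sampler_is_uniform():
    """Component draws match the enumerated composition distribution."""
    total = 5
    caps = (10, 10, 5, 2)
    support = [c for c in itertools.product(*(range(k + 1) for k in caps))
               if sum(c) == total]
    rng = np.random.default_rng(17)
    draws = sample_components(np.full(4_000, total), rng)
    seen = {tuple(row): 0 for row in support}
    for row in draws:
        seen[tuple(row)] += 1
    counts = np.array(list(seen.values()))
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    assert st.chi2(len(support) - 1).sf(chi2) > 1e-3


def test_instrument_independent_of_confounders(null_cohort):
    """With the pleiotropy knob at zero, regressing any confounder on the
    polygenic score gives a coefficient within 3 Monte-Carlo SEs of zero."""
    table = lm.pleiotropy_screen(
        null_cohort, "pgs_tc",
        ["age", "education", "bmi", "drinker", "stroke", "hypertension",
         "diabetes"])
    assert (np.abs(table["beta"]) < 3 * table["se"]).all()


def test_null_scenario_without_confounding_gives_or_one():
    params = SyntheticParams(
        n=12_000, seed=31, hdl_missing_rate=0.0,
        confounder_effects={k: (0.0, 0.0) for k in
                            SyntheticParams().confounder_effects})
    cohort = lm.apply_exclusions(lm.phenotype_cohort(simulate_cohort(params)))
    sub = lm.analytic_subset(cohort, "hdl", "cind_vs_normal").rows
    a = ((sub.hdl_status == "at_risk") & (sub.cog_status == "cind")).sum()
    b = ((sub.hdl_status == "normal") & (sub.cog_status == "cind")).sum()
    c = ((sub.hdl_status == "at_risk") & (sub.cog_status == "normal")).sum()
    d = ((sub.hdl_status == "normal") & (sub.cog_status == "normal")).sum()
    res = lm.odds_ratio_2x2(a, b, c, d)
    assert res.ci_low <= 1.0 <= res.ci_high


def test_scenarios_cover_required_regimes():
    scen = default_scenarios(n=100, seed=0)
    assert {"valid_iv_effect", "valid_iv_null", "confounded_null",
            "pleiotropic"} <= set(scen)
    assert scen["valid_iv_effect"].theta_dementia == pytest.approx(np.log(2.15))
    assert scen["valid_iv_null"].theta_dementia == 0.0
    assert scen["pleiotropic"].pleiotropy_delta > 0
    strong = scen["confounded_null"].confounder_effects
    weak = scen["valid_iv_null"].confounder_effects
    assert abs(strong["stroke"][1]) > abs(weak["stroke"][1])


def test_invalid_params_rejected():
    with pytest.raises(ValidationError):
        simulate_cohort(SyntheticParams(n=0))
    with pytest.raises(ValidationError):
        simulate_cohort(SyntheticParams(hdl_sd=-1.0))
    with pytest.raises(ValidationError):
        simulate_cohort(SyntheticParams(target_prevalence={"normal": 0.5,
                                                           "cind": 0.2,
                                                           "dementia": 0.2}))


class TestRoundTrip:
    def test_lossless_including_missingness(self, tmp_path):
        df = simulate_cohort(SyntheticParams(n=300, seed=77))
        assert df["hdl"].isna().any() and df["vocab"].isna().any()
        path = tmp_path / "cohort.csv"
        write_cohort(df, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(df, back)

    def test_missing_column_is_named(self, tmp_path):
        df = simulate_cohort(SyntheticParams(n=20, seed=1))
        path = tmp_path / "broken.csv"
        df.drop(columns=["pgs_hdl"]).to_csv(path, index=False)
        with pytest.raises(ParseError, match="pgs_hdl"):
            read_cohort(path)

    def test_empty_cohort_round_trip(self, tmp_path):
        df = simulate_cohort(SyntheticParams(n=5, seed=1)).iloc[:0]
        path = tmp_path / "empty.csv"
        write_cohort(df, path)
        back = read_cohort(path)
        assert back.empty and list(back.columns) == list(df.columns)

    def test_column_mapping(self, tmp_path):
        df = simulate_cohort(SyntheticParams(n=20, seed=2))
        path = tmp_path / "renamed.csv"
        out = df.rename(columns={"hdl": "hdl_mgdl"})
        write_cohort(out.rename(columns={"hdl_mgdl": "hdl"}), path)  # write canonical
        renamed = pd.read_csv(path).rename(columns={"hdl": "hdl_mgdl"})
        renamed.to_csv(path, index=False)
        back = read_cohort(path, rename={"hdl_mgdl": "hdl"})
        np.testing.assert_allclose(back["hdl"].to_numpy(),
                                   df["hdl"].to_numpy())
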