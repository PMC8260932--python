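"""Published summary statistics used as audit inputs.

These are the printed summary tables of a published Health and Retirement
Study analysis of clinical blood-cholesterol status and Langa-Weir
cognitive status in the European-ancestry sample (waves 2006-2012,
n = 8,781).  The microdata are restricted, but the printed counts,
odds ratios, and confidence intervals are themselves sufficient inputs for
closed-form audits: crude odds ratios can be recomputed from the
cross-tabulated counts, and the heterogeneity column can be re-derived
from the (OR, CI) pairs alone via `se_from_ci` + `heterogeneity_test`.
"""

# Cognitive status x clinical lipid level counts, European-ancestry sample.
# Cell order per contrast: (exposed cases, unexposed cases,
#                           exposed controls, unexposed controls),
# where "exposed" means the at-risk clinical level and controls are
# cognitively normal.
CRUDE_COUNTS = {
    ("hdl", "cind_vs_normal"): (353, 590, 2096, 4668),
    ("hdl", "dementia_vs_normal"): (58, 104, 2096, 4668),
    ("tc", "cind_vs_normal"): (146, 913, 1191, 6340),
    ("tc", "dementia_vs_normal"): (23, 162, 1191, 6340),
}

# Printed crude odds ratios corresponding to CRUDE_COUNTS (two decimals).
CRUDE_OR_PRINTED = {
    ("hdl", "cind_vs_normal"): 1.33,
    ("hdl", "dementia_vs_normal"): 1.24,
    ("tc", "cind_vs_normal"): 0.85,
    ("tc", "dementia_vs_normal"): 0.76,
}

# Main results grid: per (marker, contrast, tier) the printed N,
# observational logistic OR (95% CI), Wald-type MR OR (95% CI), and the
# printed P for heterogeneity.
MAIN_RESULTS = {
    ("hdl", "cind_vs_normal", "crude"):
        dict(n=7707, or_obs=1.33, ci_obs=(1.16, 1.53), or_mr=0.89, ci_mr=(0.69, 1.16), het_p=0.01),
    ("hdl", "cind_vs_normal", "demographic"):
        dict(n=7707, or_obs=1.20, ci_obs=(1.03, 1.40), or_mr=0.91, ci_mr=(0.68, 1.23), het_p=0.11),
    ("hdl", "cind_vs_normal", "health"):
        dict(n=7707, or_obs=1.15, ci_obs=(0.99, 1.35), or_mr=0.88, ci_mr=(0.65, 1.18), het_p=0.12),
    ("hdl", "dementia_vs_normal", "crude"):
        dict(n=6926, or_obs=1.24, ci_obs=(0.89, 1.71), or_mr=1.94, ci_mr=(1.13, 3.34), het_p=0.16),
    ("hdl", "dementia_vs_normal", "demographic"):
        dict(n=6926, or_obs=1.02, ci_obs=(0.72, 1.44), or_mr=2.15, ci_mr=(1.16, 3.99), het_p=0.04),
    ("hdl", "dementia_vs_normal", "health"):
        dict(n=6926, or_obs=0.97, ci_obs=(0.67, 1.39), or_mr=2.02, ci_mr=(1.08, 3.77), het_p=0.047),
    ("tc", "cind_vs_normal", "crude"):
        dict(n=8590, or_obs=0.85, ci_obs=(0.70, 1.02), or_mr=0.82, ci_mr=(0.45, 1.48), het_p=0.91),
    ("tc", "cind_vs_normal", "demographic"):
        dict(n=8590, or_obs=1.10, ci_obs=(0.90, 1.34), or_mr=0.86, ci_mr=(0.58, 1.26), het_p=0.27),
    ("tc", "cind_vs_normal", "health"):
        dict(n=8590, or_obs=1.13, ci_obs=(0.91, 1.38), or_mr=0.87, ci_mr=(0.59, 1.28), het_p=0.17),
    ("tc", "dementia_vs_normal", "crude"):
        dict(n=7716, or_obs=0.76, ci_obs=(0.47, 1.15), or_mr=0.40, ci_mr=(0.08, 1.88), het_p=0.44),
    ("tc", "dementia_vs_normal", "demographic"):
        dict(n=7716, or_obs=0.93, ci_obs=(0.57, 1.47), or_mr=0.56, ci_mr=(0.22, 1.43), het_p=0.34),
    ("tc", "dementia_vs_normal", "health"):
        dict(n=7716, or_obs=0.91, ci_obs=(0.55, 1.44), or_mr=0.57, ci_mr=(0.22, 1.47), het_p=0.39),
}

# Adjusted (demographic-tier) stage estimates for the HDL dementia contrast:
# instrument->exposure OR per SD of the HDL polygenic score, and
# instrument->outcome OR per SD.  Their log-ratio is a consistency check on
# the printed Wald-type MR OR of 2.15 (inputs are rounded to two decimals,
# so agreement is approximate).
STAGE_ADJUSTED = {
    "pgs_to_at_risk_hdl_or": 0.77,   # dementia & normal subset column
    "pgs_to_dementia_or": 0.82,
    "printed_mr_or": 2.15,
}

# Improvement chi-square statistics for the polygenic-score instruments
# (CIND & normal, dementia & normal, overall-sample columns).
IMPROVEMENT_CHI2 = {
    "hdl": (97.5, 99.8, 98.7),
    "tc": (32.6, 25.5, 32.6),
}

# Marginal calibration anchors for the synthetic-cohort generator
# (European-ancestry sample fractions).
CALIBRATION_ANCHORS = {
    "at_risk_hdl": 0.319,
    "at_risk_tc": 0.155,
    "status_normal": 0.858,
    "status_cind": 0.121,
    "status_dementia": 0.021,
}
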