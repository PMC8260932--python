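# Methods

`lipidmr` re-implements, as a tested pipeline, a one-sample Mendelian
randomization (MR) analysis of clinical dyslipidemia on cognitive
impairment in older adults, of the kind run on the Health and Retirement
Study (HRS) with restricted biomarker and genotype data.  Because the
microdata cannot ship with the package, the pipeline is exercised on a
synthetic cohort generator plus the published summary tables, which are
themselves sufficient inputs for several closed-form audits.

## Phenotypes

**Exposures.**  Blood HDL-C and total cholesterol (TC, both mg/dL) are
dichotomized at the 2018 ACC/AHA guideline cut points: at-risk (low) HDL-C
is <40 mg/dL for males and <50 mg/dL for females; at-risk (high) TC is
>=240 mg/dL.  Boundary convention: exactly 40/50 is normal HDL-C, exactly
240 is at-risk TC, read directly from the inequality signs.  The log
TC/HDL-C ratio is available as a continuous sensitivity exposure.

**Outcome.**  The Langa-Weir cognitive status is the sum of four component
scores — immediate word recall (0–10), delayed word recall (0–10),
serial-7 subtraction (0–5), backward counting from 20 (0–2) — banded as
normal (12–27), cognitive impairment non-dementia (CIND, 7–11), and
dementia (0–6).  The vocabulary score (0–10) is excluded from the total
and used only in the cognitive-domain regressions.

**Sample.**  Rows outside ages [50, 90] (inclusive at both ends), rows
flagged for a dementia-to-normal longitudinal reversal, and proxy
respondents are excluded, in that order, with per-rule counts logged.
Four complete-case analytic subsets are built per marker x contrast
(HDL/TC x CIND-vs-normal / dementia-vs-normal), complete-case on the
*union* of model covariates so that every adjustment tier within a subset
runs on the same N.  No imputation is performed.

## Models

**Observational.**  Logistic regressions of case status (CIND or dementia
vs normal) on the at-risk indicator, at three adjustment tiers: crude;
demographic (age, sex, education years, lipid-lowering medication,
measurement wave, five ancestry-specific PCs); health (demographic plus
ever-drinker, stroke, hypertension, diabetes, BMI).  Categorical
covariates use treatment coding with references sex=male, smoking=never,
wave=2006.  Fits use Newton maximum likelihood (statsmodels) with
convergence tolerance 1e-10 within 100 iterations; separation is flagged
when any standardized coefficient exceeds 15 in absolute value.  The
closed-form 2x2 odds ratio with the Woolf SE, sqrt(1/a+1/b+1/c+1/d), is
retained as an independent oracle; the acceptance suite verifies the MLE
agrees with it to better than six significant digits.  95% intervals use
z = 1.959964 throughout.  Population attributable fractions are offered in
both the Miettinen (case-based, p_c(OR-1)/OR) and Levin
(population-based, p(OR-1)/(1+p(OR-1))) forms, since published reports
often omit which was used.

**Instrumental variable.**  The instrument is a standardized polygenic
score (or, in the SNP sensitivity mode, a 0/1/2 CETP risk-allele dosage).
Both stages are logistic models on the identical subset and tier: stage
G→X regresses at-risk status on the instrument, stage G→Y regresses case
status on it.  The Wald-type ratio is beta_IV = beta_GY / beta_GX, with
first-order delta-method SE assuming zero cross-covariance between stages
— the standard single-instrument practice; Fieller intervals and
second-order terms are out of scope, as are multi-variant estimators
(with one instrument, inverse-variance weighting reduces to this ratio).
Instrument strength is the improvement chi-square,
2*(loglik_full − loglik_reduced) for the G→X model, with >10 required;
below that the engine refuses to estimate (overridable), mirroring the
practice of skipping MR when the instrument is weak.  A ratio guard also
rejects |beta_GX|/se < 2.  Heterogeneity between the observational and MR
estimates uses the interaction z-test,
z = (b−a)/sqrt(se_a²+se_b²), with two-sided normal p; log-scale SEs can be
recovered from printed intervals via (ln hi − ln lo)/(2z), which is what
the audit mode uses to re-derive entire printed heterogeneity columns.

Sensitivity machinery: a pleiotropy screen (each candidate confounder
regressed on the instrument, adjusted for the five PCs; linear for
continuous, logistic for binary), and a negative control (instrument →
impairment among participants with normal lipid levels and no
lipid-lowering medication, where a valid instrument must show no
association).

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not the HRS
itself.  Draw order, with one master seed split into named sub-streams so
toggling one knob leaves other draws unchanged:

1. Demographics and confounders: sex (58.1% female), integer age
   ~ Uniform{50..90} (respecting the exclusion window), education
   ~ round N(13.2, 2.5), BMI ~ N(28.4, 5.8), smoking
   (42.3/45.2/12.5% never/former/current), and Bernoulli flags with
   published-marginal prevalences (drinker 0.568, stroke 0.070,
   hypertension 0.613, diabetes 0.198, lipid medication 0.503, APOE-e4
   0.258).  These are documentation-level choices, not fidelity claims.
2. Instruments: pgs_hdl, pgs_tc, pgs_cog i.i.d. standard normal,
   independent of all confounders; CETP dosage ~ Binomial(2, 0.32).
3. Latent lipids: HDL-C = sex mean (50 male / 59 female)
   + 2.3·pgs_hdl + 1.5·(dosage − 2·0.32) + confounder terms
   + N(0, 15.5²), floored at 5 mg/dL; TC = sex mean (192/201)
   + 4.6·pgs_tc + N(0, 41²).  The instrument slopes are calibrated so the
   G→X log-OR is about −0.25 per SD (stage OR ≈ 0.78) and the improvement
   chi-square at n ≈ 8,000 lands near 100 — the order of magnitude of the
   published diagnostics, not an exact match.  Clinical status then follows
   from the guideline cut points, with MCAR missingness (10.4% HDL,
   0.1% TC).
4. Outcome: a baseline-category multinomial logit for
   {normal, CIND, dementia}.  Both non-normal logits share confounder
   effects (plus a small protective general-cognition PGS term and an
   APOE-e4 term on the dementia logit); the causal knobs `theta_cind` and
   `theta_dementia` multiply the **at-risk liability** — the true log-odds
   of at-risk status given genes, sex, and confounders — and the
   pleiotropy knob adds a direct instrument term.  Intercepts are solved
   at generation time (log-scale fixed point) so the marginal status split
   matches the 85.8/12.1/2.1% target.
5. Component scores: the 27-point total is drawn uniformly within the
   status band and split uniformly over the exact integer compositions
   into the four components (dynamic-programming count tables); vocabulary
   is drawn independently with 65% missingness, matching its much smaller
   published analysis N.

**Why the liability, not the binary snapshot.**  Driving the outcome by
the observed 0/1 at-risk status would make the two-stage logistic Wald
ratio structurally attenuated: for a rare outcome the estimand becomes
(e^θ−1)p(1−p)/(1+(e^θ−1)p) ≈ 0.18 at θ = ln 2.15 and p ≈ 0.32, so no
simulation could validate the estimator against its own structural
parameter.  Driving it by the at-risk liability makes both stages
(near-)correctly specified logistic models whose instrument coefficients
are proportional with factor θ, so the ratio is consistent — and it
matches the substantive reading of polygenic instruments as proxies for
*lifetime* exposure burden rather than a single cross-sectional
measurement.  Two consequences worth keeping in mind: the observational
exposure coefficient is attenuated even without confounding (the snapshot
is a noisy indicator of the liability), and `exp(theta)` is interpreted as
the causal OR per at-risk-vs-normal contrast in lifetime liability.

Because conditioning a baseline-category multinomial on two of its levels
yields that pair's exact logistic model, the generated data satisfy the
modelling assumptions of the analytic subsets by construction.

**What the generator does not emulate:** longitudinal trajectories,
linkage disequilibrium or realistic genotypes, ancestry admixture,
informative missingness, survey design, or any dependence of measurement
error on phenotype.  Passing tests therefore demonstrate the estimators'
internal validity under the stated model, not fidelity to HRS data.

## Scenarios and validation

Named scenarios: `valid_iv_effect` (theta_dementia = ln 2.15),
`valid_iv_null`, `confounded_null` (effects zero, confounding scaled
x2.5), `pleiotropic` (direct instrument→outcome path, delta = 0.3), and
`weak_instrument` (gamma ≈ 0).  The validation studies run at: 500
replicates of n = 20,000 for parameter recovery (mean log-OR within 0.05
of ln 2.15; 95% CI coverage in [0.92, 0.98]); 500 replicates of n = 8,000
for the confounded null (MR covers zero at the nominal rate while the
crude observational log-OR sits many Monte-Carlo SEs from zero); 2,000
replicates of n = 600 for the chi-square(1) calibration of the improvement
statistic (Kolmogorov distance < 0.05); and 2,000 draws for the
interaction test's type-I error (within [0.035, 0.065] at the 5% level).

Desk-scale audits need no simulation: the four published crude ORs are
refit from the printed cross-tabulated counts, and the printed
heterogeneity columns are re-derived from (OR, CI) pairs alone.  One
published heterogeneity entry (TC/CIND, health tier, printed 0.17) is not
reproducible from its own printed interval — the audit gives 0.24, while
every neighbouring row reproduces to within one unit in the last printed
digit; the tests pin the recomputed value for that row.

## Numerical choices and limitations

* z fixed at 1.959964; report ORs/CIs rounded to two decimals;
  heterogeneity p printed to two decimals, three when a value below 0.05
  would round up to the boundary (matching the mixed print precision of
  published tables).
* Logistic convergence: Newton, tolerance 1e-10, 100 iterations;
  rank-deficiency checked before fitting; zero cells in 2x2 tables raise
  rather than applying a continuity correction.
* The weak-instrument refusal (chi-square <= 10) is exclusive at the
  threshold; report cells affected by it are marked unavailable and the
  remaining cells still run.
* Report files are byte-identical across reruns of the same config and
  seed; log lines carry a step counter, not timestamps.
* The delta-method interval undercovers slightly for very weak
  instruments; the guard keeps estimation away from that regime.
* TC confounding is simplified to a sex shift plus its polygenic score;
  all shared lipid-cognition confounding flows through the HDL-C latent.
  TC-exposure MR is therefore valid but nearly unconfounded
  observationally in the defaults.
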