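# Methods notes

## Clocks

**Klemera-Doubal BioAge.** Within each sex stratum of the reference sample,
every biomarker is regressed on chronological age by ordinary least squares;
`q_i` is the intercept, `k_i` the slope (biomarker units per year) and `s_i`
the residual RMSE.  The estimator is the precision-weighted combination of the
per-biomarker implied ages with a CA anchor scaled by `s_BA`.  Conventions:

* `s_BA` is the square root of the CA variance explained by the full
  biomarker set (from a multiple regression of CA on the biomarkers in the
  stratum).  The original Klemera-Doubal derivation also offers a
  measurement-error-corrected variant; because the two circulate in applied
  work, `s_BA` is an injectable parameter (`KDMBioAge(s_ba=...)`) so either
  convention can be used.
* The regression direction is biomarker-on-age.  This is the only direction
  under which the formula's units are coherent (each term `(x_i − q_i)k_i/s_i²`
  has units of years over squared biomarker units times slope), and it makes
  subjects lying exactly on every regression line a fixed point
  (BioAge = CA), which the tests assert.
* Residual RMSEs of zero (noise-free fixtures) are floored at `1e-6` of the
  biomarker SD to avoid infinite weights; biomarkers with slope exactly zero
  are rejected.  Slope selection by t-statistic is off by default (the
  published clocks use a fixed panel) and available via `drop_flat_slopes`.
* Training and projection are strictly separated: `fit` estimates parameters
  once on the reference; `predict` applies them unchanged to any sample.

**PhenoAge.** Fixed published constants (nine biomarkers + CA, Gompertz
`γ = 0.007692696`, 120-month horizon), shipped in
`data/phenoage_coefficients.json` with a SHA-256 checksum over the canonical
payload.  Two deliberate configuration points:

* The outer denominator defaults to `0.090165`; the constant `0.09165` from
  the original PhenoAge publication is available via
  `load_coeffs(original_denominator=True)`.  Both appear in the literature
  and the package exposes the choice rather than silently preferring one.
* The coefficients are only meaningful in their native units (albumin g/L,
  creatinine µmol/L, glucose mmol/L, CRP mg/dL inside the natural log, ALP
  U/L, WBC 10³/µL).  `UnitSpec` performs multiplicative conversion from other
  lab conventions; a declared CRP detection floor is imputed as floor/√2
  before the log.  Without a declared floor, CRP ≤ 0 is an error — the
  package does not invent a fallback.
* The Gompertz risk is computed with `expm1`/`log1p` and clamped to
  `(1e-15, 1 − 1e-15)` with a warning; the clamp only matters far outside the
  physiologic range (the linear predictor of realistic panels sits around
  −8 … −3).

## Acceleration

Acceleration is the OLS residual of BA on CA over the analysis set — one
combined regression per BA measure, not sex-stratified, matching the single
acceleration per metric used downstream.  Each measure is standardized
separately (mean 0, SD 1).  The ±5 SD outlier rule is applied to raw BA in a
single pass with moments from the pre-exclusion set; values exactly on the
threshold are retained (strict inequality).  By default the rule is applied
to each BA measure and the exclusion masks are unioned (`outlier_on` restricts
it).  Quantile categories cut at the i/k interpolated sample quantiles with
boundary values assigned to the lower category; quartiles of the z-score and
of the raw residual coincide (monotone invariance, tested).

A fully noise-free cohort yields all-zero residuals; standardization then
raises rather than emitting NaNs — the documented failure path.

## Behavior score

Five components scored 0–100 by closed-left band lookup; overall score is
their arithmetic mean.  The band tables (`data/behavior_rules.yaml`) are
**reconstructions of the AHA Life's Essential 8 scheme** — diet percentile
bands, MVPA-minute breakpoints, a smoking-status × quit-duration lattice with
a 20-point secondhand-smoke penalty, sleep-hour bands, BMI bands — and are
data, not code, so a study protocol can replace them.  The diet count (0–10
recommendations met) is mapped to a cohort midrank percentile before banding;
cohorts smaller than 50 rows fall back to 10 × count so unit tests are
deterministic.

## GRS

A plain weighted sum of 12 effect-allele dosages with ln-OR weights; no
allele-frequency centering or rescaling.  Dosages must already be oriented to
the effect allele — orientation cannot be checked without a published weight
table, and the bundled `grs_weights_synthetic.tsv` is a clearly labelled
synthetic placeholder.

## Survival statistics

The Cox partial likelihood is maximized by a fully vectorized Newton-Raphson
solver with Efron tie handling; the covariance is the inverse observed
information.  The solver is written so each iteration is three dense matrix
products (the risk-set double sum collapses after exchanging the order of
summation), which makes the package's simulation studies — thousands of
refits at n up to 2×10⁵ — tractable on one core.  It is cross-checked against
lifelines (coefficients and standard errors to 1e-6, with and without ties)
and against a closed-form score-equation solution on a hand-worked dataset.
Covariates: categorical terms are dummy-coded against the first sorted level,
"unknown" kept as an explicit level; rank-deficient designs are rejected.
Adjustment sets: `model1` = age + sex; `model2` adds center, education,
income, employment, deprivation, alcohol and the behavior score; `genetic`
adds 10 genetic principal components and genotype batch.

* **PAF** uses the Miettinen case-based form `pc·(HR−1)/HR` (pc = proportion
  of cases exposed), which reproduces the published per-quartile fractions
  exactly and is the natural choice when only case counts and adjusted HRs
  are reported.
* **Splines**: Harrell's normalized truncated-power restricted cubic basis,
  three knots at the 10th/50th/90th exposure percentiles, HR referenced to
  exposure 0; overall association is a joint Wald test on the spline terms,
  nonlinearity a Wald test on the nonlinear term.  Under a linear truth the
  nonlinearity p-value is uniform (KS-tested over 200 simulations).
* **Joint grid**: one fit with 11 cell indicators against the (low GRS, Q1)
  reference.  The RERI corners (high/Q1, low/Q4, high/Q4) and their 3×3
  log-HR covariance feed the additive-interaction statistics.
* **RERI/AP**: delta-method CIs (Hosmer-Lemeshow gradients) by default; a
  percentile-bootstrap variant over log-HR draws is provided because the
  choice is rarely reported in applied papers.  `AP·HR11 = RERI` holds to
  machine precision by construction.

## Mediation

Baron-Kenny conditions (mediator model linear, outcome models Cox), then
product-method effects on the log-hazard scale: IE = a·b, DE = c′,
proportion = IE/(IE+DE), with 1 − c′/c reported as the alternative
convention.  The product method relies on a rare-outcome approximation for
hazard models, appropriate at the event fractions the generator produces
(~3%).  CIs are percentile bootstrap over subject resamples with every path
refit per replicate; a seed is mandatory.  B = 1 reproduces the non-bootstrap
point estimates exactly; sign-discordant IE and DE flag the proportion as
ill-defined rather than reporting a misleading number.

## Synthetic generator

The generator encodes the study conditions the package targets: ages uniform
on 40–69, 53.9% female, biomarker means/SDs near the cohort's reported
values with sex offsets and linear age trends, a latent frailty loading all
biomarkers in their "worse" direction so clock-style scores predict the
reference sample's mortality, baseline HF hazard 2.5×10⁻³ per person-year
with exponential event times censored at 13.5 years, HR 1.45 per SD of
acceleration, HR 1.62 per GRS point, behavior total effect log(0.76) per 10
points split a = −0.156 SD/10pt through acceleration and c′ = −0.216 directly
(≈21% mediated).  Event times are exponential because Cox estimands depend
only on rate ratios, so a constant baseline is the simplest generator that
makes every downstream statistic identifiable.

Acceleration is *realized in the biomarkers*: each subject's target residual
is induced by shifting the panel along the fitted KDM loadings
(`Δx = δ·k / c`, where `c` is the BioAge gain per unit shift), so the
pipeline must recover acceleration from the panel.  The joint-grid mode
replaces the linear hazard with a configurable 3×4 rate-ratio grid whose
empirical cell rate ratios converge to the configured values (tested at two
n).  Missingness injection flags cells independently at the configured rate
and thins each row to the per-subject cap — the documented scheme behind the
binomial count oracle.

What the generator does **not** emulate: realistic marginal shapes (skewed
CRP is clipped Gaussian), genotype LD, registry-style outcome ascertainment,
baseline-disease structure, or informative censoring.  Passing recovery tests
therefore demonstrates estimator correctness under the assumed model, not
robustness to real-data pathologies.

## Problem sizes and numerics

The recovery studies run at the sizes that make their targets identifiable
at desk scale: 20 seeds × n = 50,000 for the per-SD HR (≈1,700 events per
seed, CI half-width ≈ 0.05 on the log scale), n = 200,000 for the joint-grid
corner, 100 simulations at n = 8,000 for the additive-null RERI coverage,
and 10 seeds at n = 50,000 for mediation-proportion recovery; the bootstrap
CI demonstration uses B = 200 (point estimates are independent of B).
Newton iterations converge in 3–6 steps with step-halving; linear predictors
are clipped at ±500 and designs centered for conditioning.  All simulation
seeds are fixed constants in the tests.

## Known limitations

* The prose definition of `s_BA` (explained-variance form) is used; the
  measurement-error-corrected variant is supported only via injection.
* Behavior band tables are LE8 reconstructions, not a study's exact
  supplementary protocol.
* The mediation estimand for survival outcomes is the product-method
  log-hazard decomposition; counterfactual natural effects with
  exposure–mediator interaction are out of scope.
* Fine-Gray competing risks, time-varying coefficient models and Schoenfeld
  diagnostics beyond Wald-based checks are not implemented.
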