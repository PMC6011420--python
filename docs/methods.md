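# Methods

`gestmix` implements an analysis framework for relating mixtures of urinary
phthalate metabolites to gestational age at delivery, together with a
synthetic cohort generator that reproduces the statistical structure such a
study rests on. This note documents the models, the generator, the defaults,
and the numerical choices.

## Outcome models

Let `T_i` be gestational age at delivery in days and `E_i = I(T_i < 259)` the
preterm indicator (37 completed weeks = 259 days exactly). For an
IQR-standardized exposure summary `X̄_ik` and covariates `Z_i`, three models
are fitted:

1. **Logistic regression** `logit P(E_i = 1) = β₀ + β₁ X̄_ik + Zᵢᵀβ₂`;
   `exp(β₁)` is the odds ratio of preterm birth per IQR.
2. **Cox proportional hazards** `λ(t) = λ₀(t) exp(α₁ X̄_ik + Zᵢᵀα₂)` on the
   day scale. Every pregnancy ends in delivery, so there is no censoring and
   all subjects are events; a hazard ratio above one means *shorter* time to
   delivery. Ties (delivery times are integers-adjacent on the day scale) use
   the Efron approximation.
3. **Lognormal accelerated failure time**
   `log T_i = γ₀ + γ₁ X̄_ik + Zᵢᵀγ₂ + σε_i`. With no censoring this is
   exactly a normal linear model for `log T`; the effect is reported as the
   percent change in gestational age per IQR, `100(exp(γ₁) − 1)`.

All fits take the nested case-control design weights. The usual
information-based variance is invalid under weighting, so the logistic and
AFT fits compute an explicit sandwich whose meat uses the squared weights
(the estimating equation is `Σᵢ wᵢ sᵢ(θ) = 0`), and the Cox fit uses
lifelines' robust variance. Model-based SEs are retained on each estimate for
comparison; the robust SE is reported. Effect-scale CIs transform the
coefficient-scale Wald limits through the monotone link (`exp`, or the
percent-change map).

Covariate sets: average-exposure single-pollutant models adjust for average
specific gravity over visits 1–3, maternal age, race and education; models
for MBzP, MBP, MiBP, MEP and MCPP and all risk-score models additionally
adjust for health insurance. Repeated-measures stage-2 models drop SG (it is
a stage-1 fixed effect). Categorical covariates are reference-coded with the
most frequent level as reference.

## Exposure processing

* Non-detects are substituted by LOD/√2. The substitution is deliberately
  simple; it is adequate at the low non-detect fractions the generator
  produces (≈5% at worst) and is known to bias regression estimates when
  non-detects are common.
* Specific-gravity dilution correction `P_c = P(M_SG − 1)/(SG − 1)` with
  `M_SG = 1.015` exists for descriptive tables only. **Regressions always use
  unadjusted concentrations with SG as a covariate** — regressing on
  corrected values can bias effect estimates.
* The molar DEHP index is `ΣDEHP = Σ_k conc_k · 1000 / MW_k` (nmol/L) over
  MEHP (278.34), MEHHP (294.34), MEOHP (292.33) and MECPP (308.33 g/mol).
  ΣDEHP is molar-summed per visit, log-transformed, then visit-averaged,
  mirroring the single-metabolite handling (the alternative — averaging
  before the log — is a configuration away but not the default).
* The average-exposure summary is the mean of natural-log concentrations over
  visits 1–3. Visit 4 is excluded because early deliveries make its
  availability informative of the outcome.
* IQR standardization divides by `Q3 − Q1` (linear-interpolation / type-7
  quantiles; configurable) without centering, computed unweighted on the
  analysis sample, so coefficients read "per IQR".

## Risk scores

Subset selection tames the collinearity of the nine metabolites:

* **Correlation screen** — blocks are connected components of the graph with
  an edge where |r| > 0.5 (Pearson correlation of mean log SG-corrected
  exposures); each block keeps only its member with the largest
  single-pollutant Cox |z|. With the default generator the DEHP block
  collapses to one member, leaving six metabolites.
* **Stepwise** — bidirectional AIC-stepwise IPW logistic regression of the
  preterm indicator with covariates forced in. AIC admits a null variable
  with probability ≈0.16 per single comparison, and the greedy best-of-nine
  search inflates that; simulations here show null subsets of median size 2.
  This is accepted behaviour of AIC stepwise, not a defect.

**ERS** weights are the metabolite coefficients of one *joint* IPW logistic
model on the selected subset; a joint fit avoids double-counting correlated
metabolites (configurable to single-pollutant weights). The score
`RS_i = Σ w_k x_ik` on IQR-standardized summaries is then itself
IQR-standardized. ERS is estimated and applied on the same data, so its
apparent effects are optimistic — external validation is out of scope here.

**WQS** quantile-scores each exposure into quartiles (0–3; ties at a
cutpoint fall in the lower category) and maximizes the IPW logistic
likelihood of `β₀ + β₁ Σ w_k q_ik + Zᵀφ` under `w ≥ 0`, `Σw = 1`, `β₁ ≥ 0`
(direction of harm = higher preterm odds) with SLSQP. Weights are averaged
over `B = 100` bootstrap resamples with `β₁ > 0` that converged (all
converged resamples, with a warning, if none), then `β₁` is re-estimated on
the full data with the weights frozen. No train/validation split is used by
default: at nested case-control sizes (~480) the precision cost of a split
outweighs the overfitting it prevents; a gWQS-style split remains available.
These settings (q = 4, B = 100, no split, positive direction,
mean-over-positive-bootstraps) are this package's documented defaults.

Quartile analyses cut the standardized score at design-weighted 25/50/75th
percentiles (weighted quantiles use weight-expanded-sample semantics, so
integer weights reproduce numpy's linear-interpolation quantiles on the
expanded sample) and contrast Q2–Q4 against Q1 in all three models.

## Repeated-measures arm

Stage 1 fits the random-intercept model
`y_ij = φ₀ + φ₁ T_ij + φ₂ SG_ij + b_0i + ε_ij` to all available visits
(1–4; the mixed model handles unequal visit counts), where `T_ij` is the
gestational week at sampling (uncentered) and `SG_ij` the visit's specific
gravity. Estimation is REML (unbiased variance components) via statsmodels
MixedLM, first with BFGS at gradient tolerance 1e-10, then statsmodels'
default and conjugate-gradient fallbacks; if all fail, a method-of-moments
one-way ANOVA estimator on fixed-effect residuals is used with a logged
warning. The BLUPs `b̂_0i` are shrinkage estimates of subject-level exposure
(subjects with fewer visits shrink harder); IQR-standardized BLUPs are the
stage-2 predictors. For balanced data the REML solution coincides with the
closed-form one-way ANOVA estimators, which the tests verify to 1e-6.

The per-visit ERS path applies the average-arm subset and ERS weights to
visit-specific log concentrations (standardized by the average-arm IQRs),
then runs the same LMM→BLUP→outcome chain. WQS is excluded from this arm:
the stage-1 response must be continuous and the quantile-scored WQS is
discrete. Re-estimating ERS weights per visit was considered and rejected —
visit-level weights would be far noisier and would break comparability with
the average arm.

Because the BLUP is a noisier summary than the three-visit mean (it folds in
variance-component estimation and visit-4 measurements), stage-2 estimates
based on it carry extra sampling variance; simulations here reproduce the
attenuation of repeated-measures estimates relative to the average-exposure
arm in the majority of replicates.

## Synthetic cohort generator

The generator emulates a prospective pregnancy cohort (default n = 1181)
with up to four urine-collection visits at median gestational weeks
9.71/17.9/26.0/35.1 (uniform jitter ±2.5/2.0/1.6/1.6 weeks).

**Exposures.** Log concentrations decompose as
`log X_ijk = b_ik + λ(SG_ij − 1.015) + e_ijk` with subject effects
`b_i ~ MVN(μ, Σ_b)` and within-visit noise sharing the between-subject
correlation structure (short-term sources — diet, dilution — are shared
across metabolites). The dilution term is *linear* in SG (slope λ = 55 per
unit SG) so that models that adjust for SG as a linear covariate — the
regression contract — see exactly the generative signal; the descriptive
`P(M−1)/(SG−1)` correction is then only approximately exact, which mirrors
real practice. Per-metabolite within variance is set to
`total · (1 − ICC) − λ²·Var(SG)`, so the observed one-way ANOVA ICC matches
the configured ICC (defaults 0.19–0.61, DEHP metabolites least stable, MEP
most). The default between-metabolite correlation puts the four DEHP
metabolites at r = 0.85 (pairwise observed correlation of mean exposures
>0.5), MBP–MiBP at 0.45, MEP nearly independent. Default geometric means are
realistic µg/L values (MEP highest at ~120 µg/L); total log-SD is √1.21 ≈
1.1. Default LODs are set from the marginal log-normal so that ≈4.7% of MEHP
values (and ≤2% of the others) fall below detection; values strictly below
the LOD are flagged and stored at the LOD, with substitution deferred to
exposure processing (a value exactly at the LOD counts as detected).

**Delivery times.** Two modes:

* `term_preterm_mixture` (default) — a term component N(277, 8.5²) days and
  an early component N(246, 12²), with exposure acting on the log-odds of
  early membership (defaults put the largest coefficient on MECPP). Baseline
  membership 0.095 yields a marginal preterm fraction of ≈0.11 — the
  130/1181 design — and a heavily left-skewed marginal distribution.
* `aft_lognormal` — `log T_i = γ₀ + Σ_k γ_k x̄_ik + Zᵀγ_Z + σε` with
  `x̄_ik` the subject's mean pre-dilution log concentration over visits 1–3
  and σ = 0.045. This mode is the exact generative counterpart of the AFT
  analysis model and is the ground truth for recovery tests; those runs
  disable LOD censoring and random visit missingness, because LOD/√2
  substitution and missing visits are known attenuating perturbations that
  would otherwise confound the estimator check.

**Attrition and sampling.** Visits at or after delivery are removed (this
alone gives preterm subjects markedly lower visit-4 availability); visits
2–4 are additionally missing at random (defaults 10/12/10%); visit 1 never
is, since it defines cohort entry. The nested case-control sample takes all
preterm cases (weight 1) and `n_controls` uniform draws from non-cases with
a visit-1 sample plus at least one later visit, each weighted by
(eligible non-cases)/n_controls; controls are drawn after outcomes are
known, matching a retrospective nested design. The weighted sample size
equals cases + eligible non-cases.

**What the generator does not emulate:** dietary/temporal exposure sources,
gestational-age measurement error, twin pregnancies, covariate–exposure
confounding (covariates are independent of exposure), and any nonlinearity
or interaction in the exposure–outcome surface. Passing recovery tests
therefore demonstrate estimator correctness under the stated model, not
robustness to these real-data features.

## Numerical choices and degenerate inputs

* Quantiles: numpy "linear" (type 7) everywhere, configurable.
* Logistic fits flag (quasi-)separation when any coefficient × column-SD
  exceeds 15; the sandwich variance clips negative numerical diagonals at 0.
* A constant exposure in the Cox model returns coefficient 0 with infinite
  SE (the partial likelihood is flat) rather than an optimizer failure.
* Zero-IQR exposures, fewer than 4 distinct quartile values, empty quartiles,
  non-positive concentrations after substitution, and SG ≤ 1 all raise
  informative errors.
* Seeds: every stochastic component takes an explicit seed; cohort
  sub-streams (attrition, sampling) are spawned from the SimTruth seed, so
  identical truth ⇒ byte-identical cohorts.

## Problem sizes used in the checks

Recovery and coverage run 500 replicates of n = 2000 cohorts (bias assessed
against 2 Monte-Carlo SEs; coverage band 93–97%); IPW consistency uses 100
replicated designs at the cohort size 1181; WQS behaviour uses 15–20
bootstrap resamples within 15–30 replicates at n = 400–500; amplification
uses 16 replicates and the arm-attenuation share 16–24 replicates.
Stochastic tolerances are set at 2–3 Monte-Carlo SDs measured by simulation.
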