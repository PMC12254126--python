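# Methods

`mrsurv` implements a one-sample Mendelian-randomization (MR) analysis of a
continuous exposure (body-mass index, BMI) on cause-specific mortality in a
prospective cohort, together with a synthetic cohort generator whose causal
structure is fully known. This note records the statistical model behind
each stage, the parameters that matter, and the design decisions taken where
more than one reasonable choice existed.

## The estimators

**Allele scores.** An instrument is an additive weighted allele score
`S_i = Σ_j w_j d_ij`, with `d_ij` the dosage of variant `j`'s effect allele
in individual `i` and `w_j` an externally supplied per-allele weight. Dosages
whose coded allele disagrees with the panel's effect allele are flipped to
`2 − d`; missing dosages are mean-imputed at `2p_j` by default, with a hard
failure above 10% missingness per variant. Scores are standardized (mean 0,
SD 1) within each analysis subset after exclusions, so every downstream
coefficient is "per SD of score" before conversion to exposure units.

**First stage.** Ordinary least squares of the exposure on the standardized
score plus covariates (entry age and genetic principal components by
default). Instrument strength is summarized by the partial R² of the score
and the partial F-statistic `F = (n − k − 1) R²_p / (1 − R²_p)`; an F below
10 flags (never suppresses) downstream ratios. Supporting diagnostics are
the table of cohort characteristics across fifths of the sex-specific score
distribution and greedy p-value-ordered LD clumping (default r² threshold
0.01, "relaxed" sensitivity 0.1) for re-building the panel.

**Second stage.** Cause-specific Cox proportional-hazards regression on the
attained-age timescale with delayed entry at recruitment. Deaths from the
target cause (or any of its sub-causes) inside the half-open age window
[35, 75) are events; competing-cause deaths are censored at the death age
and deaths at or beyond the window edge are censored there. Ties are
handled by the Efron approximation; the partial likelihood is maximized by
Newton iterations to a gradient norm below 1e-8 (at most 100 iterations,
with step-halving). The engine is a vectorized implementation whose
coefficients, standard errors, and log-likelihood agree with
`lifelines.CoxPHFitter` to ~1e-6 on tied, left-truncated data (tested); it
exists because the bootstrap and replicate studies need tens of thousands of
fits.

**Wald ratio and pooling.** The causal log hazard ratio per exposure unit is
`β_IV = β_zy / β_zx` with the two-term delta-method standard error
`se_IV = sqrt(se_zy²/β_zx² + β_zy² se_zx²/β_zx⁴)`. Analyses run separately
by sex; sexes are pooled by inverse-variance weighting on the
log-HR-per-unit scale, exactly in that order. Results are reported as
hazard ratios per 5 kg/m² with CI `exp(5(β ± 1.96 se))`.

**2SLS.** Stage 1 regresses the exposure on the score(s) plus covariates;
stage 2 fits the Cox model on the fitted values plus covariates. The
second-stage SE is reported without a first-stage correction — the
Wald-ratio delta SE is the primary inferential path, and the mediation
bootstrap covers joint uncertainty where it matters.

**Mediation.** The total effect is 2SLS with the BMI score alone. For the
direct effect, genetically predicted BMI and genetically predicted diabetes
liability enter one Cox model jointly, with *multivariable* stage-1 fits:
each exposure is regressed on both scores. With disjoint instruments this
cross-instrumentation is necessary — if each exposure is predicted only from
its own score the two predictors are orthogonal by construction and the
adjustment cannot attenuate anything (that variant is available via
`cross_instruments=False`, and a probit stage 1 for diabetes liability via
`diab_stage1="probit"`). The proportion mediated is
`(log HR_total − log HR_direct) / log HR_total`, undefined when
`|log HR_total| < 0.01` (resamples below the floor are dropped and
counted). Its CI is a bias-corrected (BC, not BCa) percentile bootstrap over
individual-level resamples, recomputing both stages per resample;
acceleration estimation by jackknife at cohort scale was judged an unforced
cost. More than 20% failed resamples flags the CI unreliable.

**Two-sample sensitivity estimators.** Per-variant marginal associations
(linear for the exposure, Cox for mortality, same covariates) are
harmonized so every `β_zx ≥ 0`. IVW is the origin-constrained weighted
regression of `β_zy` on `β_zx` with weights `1/se_zy²`, with multiplicative
random-effects SE inflation when Cochran Q exceeds its degrees of freedom.
The weighted median orders per-variant ratios, weights them by
`(β_zx/se_zy)²` (first-order delta ratio variance), and interpolates where
the centred cumulative weight crosses 50%; its SE is a seeded parametric
bootstrap of the summary statistics. MR-Egger frees the intercept; the
slope is the causal estimate, the intercept the directional-pleiotropy
test (SEs with multiplicative overdispersion never deflated below 1), and
I²_GX is reported as the regression-dilution diagnostic. Both sides are
computed in the same cohort by default (the one-sample situation); a 50/50
sample split is available behind a flag.

**Non-linear MR.** Residual stratification forms equal-size quantile groups
of the exposure minus its instrument-predicted component; doubly ranked
stratification cuts the score order into consecutive pre-strata of size `q`
and sends each pre-stratum's `k`-th exposure-ranked member to stratum `k`
(a remainder pre-stratum of size `r` maps its `j`-th member to stratum
`floor((j + ½)q/r) + 1`; the method refuses when `n < q²`). Per-stratum
Wald ratios use stratum-specific first stages; log-linearity is probed by
Cochran Q across strata and an IVW linear trend of the stratum estimates on
stratum mean exposure. Default `q = 10`. Strata below the event floor merge
into their lower neighbour with a warning. The negative-control diagnostic
regresses entry age (linear) or sex (logistic) on the score within each
stratum; the table is emitted without an automated verdict, since no
quantitative threshold for "distortion" is established.

## The synthetic cohort

The generator emulates the statistical structure such an analysis faces in
an admixed middle-aged cohort: ~68% women; measured BMI 28.0 (SD 4.2) kg/m²
in men and 29.7 (5.2) in women; 18% prevalence of any diabetes with 13/18
diagnosed; admixture proportions Beta(4, 2) (median ≈ 0.69); entry ages
normal(50, 11) truncated to [35, 90); ~10% cumulative mortality over 20
years of follow-up at reference covariates; and a hierarchical
cause-of-death mix (vascular-metabolic: vascular {cardiac, cerebrovascular,
other}, renal, hepatobiliary, acute diabetic crisis; non-vascular-metabolic:
cancer, respiratory, infective, external/other) proportioned like the death
counts of a large urban Mexican cohort, with renal and acute-crisis causes
up-weighted 3× in diabetics.

**Genotypes.** Variants are independent (no LD; clumping is exercised on a
synthetic r² overlay instead). Allele frequencies are Uniform(0.05, 0.95)
with a per-variant linear ancestry shift of random sign and magnitude up to
0.20 — typical of continental frequency differentials — so the leading
principal component of the centred dosage matrix tracks ancestry (|r| > 0.9
with the default 724 + 200 variant panels). Dosages are posterior-mean style
(imputation quality 0.95) unless hard calls are requested. Four PCs are
computed by randomized SVD with a deterministic seed and sign convention.
Panel weights are scaled so the implied score variance under Hardy-Weinberg
(`Σ w² 2p(1−p)`) equals the target R² (0.03).

**Phenotypes.** True lifelong BMI is a sex intercept plus the score (0.70
kg/m² per SD in men, 0.94 in women — with the Table-calibrated SDs these
give per-sex first-stage R² of 2.8%/3.3%), an ancestry effect (1 kg/m² per
unit admixture), a latent standard-normal confounder (1 kg/m² per SD), and
Gaussian noise sized per sex to hit the target SD. Diabetes arises on a
unit-variance liability: 0.08 liability SD per kg/m² of true BMI (chosen so
the prevalence gradient across score fifths is ~5 percentage points),
0.25 per SD of the diabetes score, thresholded empirically at 18%
prevalence, with the most severe 13/18 of diabetic liability "diagnosed".
Measured BMI subtracts a weight-loss delta (default 1.5 kg/m²) in diagnosed
diabetes only — self-knowledge plausibly precedes weight change — and adds
0.3 kg/m² measurement noise.

**Survival.** Event times come from a Gompertz-baseline (shape 0.09/yr)
proportional-hazards model on attained age, sampled by inverse transform of
the conditional cumulative hazard given survival to entry; administrative
censoring at entry + 20 years and at age 90. The linear predictor combines
the direct BMI effect, an optional quadratic term (the J-shape generator),
the severity-weighted diabetes state (undiagnosed diabetes carries 1/3 of
the diagnosed log hazard), the confounder (0.25/SD), sex (0.40 for men) and
ancestry (0.15/unit).

**Calibration of the causal truth.** `causal_loghr_per_unit` (default 0.10)
is defined as the estimand of a correctly specified MR analysis on the
generated cohort, and `mediated_fraction` (default 0.5) as the share of it
recovered as mediated by the two-score procedure. Three facts make naive
coefficient-setting wrong by 20-50%: the mediated pathway acts through a
binary state with a large hazard multiplier, so its log-hazard slope exceeds
the mean-state slope (Jensen); the partial likelihood learns from events and
depletes high-frailty individuals over follow-up (noncollapsibility); and
the first-stage denominator uses measured BMI, which diagnosed-diabetes
weight loss attenuates by a factor κ = 1 − δ·dP(diagnosed)/dBMI. The
generator therefore computes the large-sample Cox estimand directly: on an
age quadrature over the analysis window it evaluates the event-weighted
derivative of the log of the at-risk-pooled marginal hazard
`Σ_i E[r_i e^{−r_i ΔH_i}] / Σ_i E[e^{−r_i ΔH_i}]` (expectations over the
liability noise, aggregated within sex, since the analysis is
sex-stratified), and solves for the diabetes coefficient so the total
gradient equals κ·causal, and for the direct BMI coefficient so the
fixed-liability gradient equals (1 − f)·κ·causal (bracketed root finding on
the rising branch, alternated for a few fixed-point iterations). Replicate
studies show the pooled Wald ratio then recovers 0.10 with |bias| below
~0.005 and ~95% CI coverage. Residual approximation error (covariate
adjustment, finite-sample ratio bias) is at the few-thousandths level.

**Planted defects** (all off by default): a quadratic log-hazard term in
BMI (default 0.01 per (kg/m²)² when used — curvature whose hazard-gradient
change per 5 kg/m² is comparable to the linear effect, i.e. a clearly
J-shaped exposure-response); directional pleiotropy, assigned to the
fraction of BMI variants with the *weakest* primary-trait effects
(mirroring the enrichment of pleiotropy-dominated signals among borderline
GWAS hits, and the regime in which the weighted median's majority-weight
robustness actually operates) and oriented along each variant's
BMI-increasing allele; a score-dependent entry-age truncation (high-score
individuals cannot enter old) for the negative-control diagnostics; and
optional sibling blocks sharing half their dosage deviations.

**Exclusions.** Four independent Bernoulli flags (QC failure 13.3%, age ≥90
0.5%, implausible anthropometry 1.1%, uncertain linkage 1.5%) applied
sequentially, each count conditional on surviving prior steps, then a split
into the 35-74 analysis set and the 75-89 older set.

**Determinism.** One global seed; every sub-generator draws from a named
substream (CRC-keyed `SeedSequence`), so adding a generator never perturbs
the others, and identical parameters reproduce byte-identical outputs.

## What the generator does not emulate

Linkage disequilibrium (variants are independent); haplotypes and phasing;
relatedness beyond the optional sibling blocks; calendar-time effects and
secular mortality trends; cause-of-death misclassification; non-fatal
outcomes; real allele-frequency spectra or real GWAS weights (weights are
synthetic stand-ins for the externally estimated ones the analysis takes as
input). A test passing on these cohorts therefore demonstrates the
estimators' statistical behaviour under the assumed structure, not
robustness to LD misspecification or cryptic relatedness.

## Problem sizes in the test suite

The statistical validation runs at sizes chosen to give the checks adequate
power on a single CPU: instrument recovery on one cohort of 50 000 with the
full 724-variant panel; Wald-ratio coverage over 100 replicates of 10 000
(100-variant panels); mediation recovery over 50 replicates of 20 000 with
200 bootstrap resamples (without PC covariates — the per-replicate ancestry
confounding is sign-random and averages out of the recovery check, and the
two-stage machinery under test is unchanged); estimator agreement on one 20 000 cohort and
pleiotropy separation over 8 replicates of 50 000 with 50-variant panels;
non-linear calibration over 50 log-linear replicates of 15 000 and power
over 50 quadratic replicates of 50 000 at q = 5. Smaller panels than the
default are used where only the score (not panel-level resolution) matters,
since score behaviour depends on total variance explained rather than
variant count.

## Known limitations

The 2SLS second-stage SE ignores first-stage uncertainty (documented;
negligible at F in the hundreds). Hazard ratios are non-collapsible, so
"the" causal log HR is estimand-dependent; the generator pins it to the
sex-stratified, PC-adjusted, window-restricted Cox estimand described
above, and other analysis choices recover slightly different numbers. The
proportion mediated is a ratio statistic and behaves badly when the total
effect nears zero; the floor-and-drop rule is this package's explicit
choice. The weighted median's robustness claim presumes invalid instruments
carry a minority of the *weight*; when 30% of instruments invalid by count
carry 30% of the weight one-sidedly, no median-type estimator is unbiased
at finite per-variant precision.
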