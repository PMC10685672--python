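# Methods

This note documents the statistical models implemented in `osipheno`, the
assumptions they make, and the design of the synthetic cohort generator used
to exercise them. Nothing here is an empirical claim about real patients;
all numbers quoted are properties of the synthetic generator or of the
estimators themselves.

## 1. Synthetic cohort generator (`osipheno.synth`)

The generator emulates a cohort of mechanically ventilated ICU patients
whose oxygen saturation index (OSI = FiO2 × mean airway pressure × 100 /
SpO2) is sampled every 6 hours over the first 5 ventilation days (20
gridpoints, 0–114 h).

**Latent classes.** Each patient belongs to one of four latent classes with
shares (0.649, 0.089, 0.207, 0.054), in generator indexing: *low-stable*,
*ascending*, *descending*, *high-stable*. Class-specific mean OSI is a
polynomial in time (days): intercepts 5.22 / 9.38 / 12.00 / 17.07 with
slopes 0 / +1.18 / −1.05 / 0. Observed OSI adds a patient-level random
intercept (SD 1.0) and i.i.d. residual noise (SD 2.0). The observed series
is also decomposed into plausible SpO2, FiO2 and MAP channels so the OSI
computation itself can be tested on raw inputs.

**Baseline covariates.** Twenty-one covariates (8 continuous, 10 binary,
ethnicity with 3 levels, baseline OSI, and the ARDS mediator) have
class-specific means/prevalences whose *orderings* follow the severity
gradient of the phenotypes (e.g. PEEP, plateau pressure and APS-III rise
from the low to the high class). Between-class gaps are deliberately
moderate relative to the within-class spread so that every class retains
support throughout covariate space — the positivity condition that IPTW
requires. Continuous covariates additionally load on a shared per-patient
severity factor, producing realistic within-class correlation (and hence
non-trivial VIF diagnostics).

**Mediator and outcome.** ARDS is Bernoulli with class-specific prevalence
(0.549 / 0.701 / 0.689 / 0.771), calibrated by root-finding so the
*expected* prevalence matches the target exactly given the covariate
effects. ICU death is logistic in class (calibrated intercepts for expected
mortalities 0.2069 / 0.3156 / 0.2129 / 0.4098), ARDS (log-odds log 1.456),
and severity covariates. Ventilation duration is 5 + exponential days
(class-specific scale, capped at 28); deaths occur from day 5 with a
geometric daily hazard of 0.15 (capped at day 30). Ventilator-free days
(VFD) use the standard convention: death before final liberation scores 0.

**What the generator does not model.** Informative (MAR/MNAR) missingness
(only MCAR masking is provided); competing discharge risks; time-varying
covariates or treatments; measurement error in SpO2/FiO2/MAP beyond i.i.d.
noise; inter-ICU clustering.

## 2. Group-based trajectory model (`osipheno.gbtm`)

A finite mixture of polynomial mean trajectories: conditional on class k,
the observed OSI at time t is Gaussian with mean Σ_j β_kj t^j and a shared
residual SD. Estimation is by EM:

- E-step: posterior class memberships from the Gaussian likelihood of each
  patient's observed gridpoints (missing points simply drop out).
- M-step: class shares from posterior sums; polynomial coefficients by
  posterior-weighted least squares on a time-centered design (numerically
  stable; coefficients are un-centered for reporting); pooled σ².
- Multiple starts: k-means on per-patient (mean, slope) summaries with
  jitter; the best converged log-likelihood wins. The log-likelihood is
  non-decreasing across iterations by construction.

**Diagnostics.** BIC = −2ℓ + p·ln n; relative entropy
1 − (−Σ p log p)/(n ln K); average posterior probability (APP) per modally
assigned class; class shares. A candidate is *admissible* only if every
share ≥ 5% and every APP ≥ 0.7.

**Model selection** is two-stage: (1) fit K ∈ {2,3,4} with quadratic
shapes, reject inadmissible candidates, choose the admissible K with lowest
BIC; (2) start from cubic shapes and iteratively drop each class's highest
order term while its Wald p ≥ 0.05, never below linear. Fitted classes are
always reported in canonical order of increasing mean fitted OSI, so class
labels are comparable across runs (note this puts the *descending* class
before the *ascending* one, since its 5-day mean is lower).

## 3. Causal estimation (`osipheno.causal`)

**Propensity and weights.** Multinomial logistic (or gradient-boosted)
propensity over the 21-covariate confounder set; probabilities are clipped
to [1e-3, 1−1e-3] and renormalized. IPTW weights are 1/ê_{i,Z_i},
optionally stabilized by marginal class shares and/or percentile-truncated.

**Balance.** Standardized mean differences are the maximum over class
pairs; continuous covariates use the pooled (weighted, bias-corrected)
variance, binary ones use √((p_a(1−p_a)+p_b(1−p_b))/2). SMD > 0.1 flags
imbalance.

**Known limitation on the default cohort.** Baseline OSI is derived from
the class-defining trajectories themselves (class means ≈5 vs ≈17 with SD
≈2), so it nearly separates the exposure groups: its propensity
contribution hits the clip, a handful of patients receive extreme weights,
and baseline OSI — together with several severity covariates — remains
imbalanced after weighting. This is a genuine positivity failure intrinsic
to a trajectory-defined exposure, not an estimator bug; the balance
*property* (weighting reduces the number of imbalanced covariates under a
correctly specified propensity with adequate overlap) is verified on a
controlled confounded simulation in the test suite. The pipeline uses
stabilized weights by default to moderate (not hide) the tail.

**Doubly robust step.** Weighted logistic regression of death on phenotype
indicators plus an adjustment set — none (IPTW only), the still-unbalanced
covariates, or all covariates — with a sandwich (HC0) variance treating the
weights as fixed. Adjustment covariates are standardized; VIF (1/(1−R²))
is reported for multi-covariate adjustment sets, flagged above 5.
Subgroup analyses refit per stratum and test phenotype × stratum
interaction by a likelihood-ratio test on the pooled weighted model (a
pseudo-likelihood approximation under weighting).

## 4. Mediation (`osipheno.mediation`)

Quasi-Bayesian counterfactual simulation for a binary treatment (the
poor-prognosis phenotype indicator), binary mediator (ARDS) and binary
outcome (death): logistic models M ~ T + X and Y ~ T + M (+ T×M) + X are
fitted; parameters are drawn from their asymptotic normal; for each draw
the four counterfactual risks E[Y(t, M(t'))] are computed by averaging over
the empirical covariate distribution. ACME and ADE are averaged over the
two treatment arms, so ACME + ADE equals the total effect exactly on the
risk-difference scale, draw by draw. Percentile intervals come from the
draws; odds-ratio versions use the odds of the averaged counterfactual
risks. Assumptions: sequential ignorability (no unmeasured
treatment-outcome or mediator-outcome confounding) and correctly specified
logistic models.

## 5. Prediction (`osipheno.predict`)

The poor-prognosis model: SMOTE on the training split only (synthetic
minority points are uniform interpolations between standardized nearest
minority neighbors), LASSO screening at the cross-validated deviance-
minimizing penalty (saga solver; C = 1/(nλ)), an unpenalized logistic fit
on the selected features, and a nomogram rendering whose point scale is an
exact affine transform of the linear predictor (risk round-trips to within
floating-point error). Evaluation: rank-formula AUC with DeLong intervals,
decile calibration with the Hosmer–Lemeshow test (df = g−2, valid for
internally fitted models), and decision-curve net benefit
TP/N − FP/N·p_t/(1−p_t) against treat-all/treat-none.

## 6. Secondary outcomes (`osipheno.outcomes`)

VFD as above; Kaplan–Meier per phenotype with administrative censoring at
the horizon (21 days), optional IPTW weights entering through weighted risk
sets, Greenwood-style intervals (reported descriptively under non-integer
weights); a weighted log-rank test referred to χ²(G−1) as an
approximation.

## 7. Imputation (`osipheno.preprocess`)

Covariates with >15% missingness are dropped. The rest are imputed by
chained equations: linear regression with Gaussian residual draws for
continuous columns, (multinomial) logistic draws for binary/nominal ones,
visited in order of increasing missingness; observed cells are never
modified. Estimates across the m completed datasets pool by Rubin's rules
(T = W + (1+1/m)B, Barnard–Rubin-style df). The imputation draws are proper
in the residual-noise sense but omit parameter uncertainty (no posterior
draw of the regression coefficients), a common simplification that slightly
understates between-imputation variance.

## 8. Pipeline and reproducibility (`osipheno.pipeline`)

Stage seeds derive from the global seed by CRC-32 of `"{seed}:{stage}"`
(stable across processes and platforms, < 2³¹). All artifacts are
delimited text or JSON with sorted keys; rerunning a config reproduces
`report.json` byte-for-byte. The train/validation split in the prediction
stage is a random 55/45 partition, standing in for the two-database
external validation such studies use.
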