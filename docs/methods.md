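# Methods

This document describes the statistical methods implemented in `trclust`, the
defaults they ship with, and the design of the synthetic data generator used
to validate them.

## 1. Trajectory preparation (`trclust.prep`)

Raw HAM-D total scores are integer-valued, bounded below by 0, and strongly
right-skewed near remission. Scores are analyzed as `ln(raw + 0.5)`; the 0.5
offset keeps a score of 0 finite and approximately variance-stabilizes the
scale. `inverse_transform` maps fitted values back via `round(exp(y) − 0.5)`
clipped to the instrument range.

Two naturalistic visit designs are built in: `MARS` (weekly through week 6,
then weeks 8, 10, 12, 14, 16) and `GENDEP` (weekly through week 12). Observed
series are regularized onto the weekly grid by linear interpolation **on the
raw scale** between observed visits (never extrapolated beyond the last
observation), then transformed. Interpolating on the raw scale matches how a
clinician would read the chart and avoids the convexity bias of interpolating
logs.

Eligibility requires a baseline (week 0) score of at least 14 — mixtures of
improvement slopes are not identifiable among patients who are barely ill at
intake. Exclusions are reported per patient with a reason
(`prep.filter_eligible`).

## 2. Mixture of linear regressions (`trclust.mixture`)

### Model

Patient *i*'s ln-scores are modeled as class-conditionally independent
Gaussians around a class-specific line: class *k* has intercept, slope,
residual SD and weight. The class is latent per patient (not per
observation), so all of a patient's observations share one class.

### Estimation

EM operates on per-patient sufficient statistics
(n, Σt, Σt², Σy, Σty, Σy²); the Gaussian log-likelihood and the weighted
least-squares M-step are exact linear functions of these, so both steps are
single matrix products and the cost per iteration is independent of series
length. Equivalence with row-level computation is enforced to 1e-10 by
oracle tests.

- **Initialization:** random hard partition of patients with every class
  non-empty, followed by an M-step. With `n_restarts` (default 200) seeded
  restarts, sub-seeds are spawned deterministically from the user seed.
- **Convergence:** relative log-likelihood change below `tol` (default 1e-8),
  at most `max_iter = 500` iterations. The observed-data log-likelihood is
  non-decreasing by construction; tests assert it.
- **Degeneracy guards:** residual SDs are floored at 1e-4, a class whose
  effective weight falls below one patient marks the run degenerate, as does
  a near-singular normal-equations determinant. Degenerate or non-converged
  runs are excluded; if no restart survives, that *K* is reported as
  non-convergent rather than returning a spurious fit. In practice this is
  how implausibly small or large *K* eliminate themselves.

### Model selection

For each converged *K*: BIC = −2ℓ + p·ln N with p = 3K + (K−1) free
parameters and N the number of patients, and ICL = BIC + 2·ENT where
ENT = −Σᵢₖ zᵢₖ ln zᵢₖ is the posterior assignment entropy. ICL penalizes
solutions whose extra classes merely split well-mixed patients; the selected
model minimizes ICL over the candidate range (default 4–10, configurable).
Components are reported sorted by ascending slope (fastest improvement
first), ties broken by intercept.

## 3. Projection (`trclust.projection`)

`assign_fixed` classifies any regularized cohort under **frozen** parameters
(a single E-step; no refitting), reporting mixture and classification
log-likelihoods, entropy and ICL. `truncation_curve` re-classifies each
patient from only their first *m* weekly values (m = 1 … design maximum) and
reports the Pearson correlation between cluster-derived slopes under
truncated versus full information — a measure of how early the eventual
response class is determined. Windows in which either assignment is
single-class have undefined correlation and are reported as NaN with a
warning. `proportion_test` compares class proportions between two cohorts
with a Pearson chi-square homogeneity test on the K×2 table (no continuity
correction).

## 4. Outcomes (`trclust.outcomes`)

Standard endpoint definitions: **response** = ≥ 50% decrease from baseline at
the last available visit; **remission** = raw score < 10 at the last
available visit. Each patient's **individual slope** is the OLS slope of
their ln-values over the weekly grid. Class differences in continuous
baseline covariates are tested with one-way ANOVA; effect size is Cohen's
f = √(η²/(1−η²)), labeled small/medium/large at 0.10/0.25/0.40. A Gaussian
likelihood-ratio test (n·ln(SS₀/SS₁) against χ²(K−1)) provides a
regression-based alternative that extends to non-Gaussian items.

## 5. Prediction (`trclust.prediction`)

Random-forest regression predicts two response-speed targets from baseline
data: the individual OLS slope and the cluster-derived slope (the fitted
slope of the assigned class). Four nested feature sets are defined:

| model | features | D |
|---|---|---|
| 0 | baseline clinical/demographic items | 50 |
| 1 | model 0 + HAM-D single items | 71 |
| 2 | model 0 + early partial response (HD_2WE) | 51 |
| 3 | model 1 + HD_2WE | 72 |

`HD_2WE` flags a ≥ 25% raw-score reduction by week 2 (inclusive), computed
from the regularized trajectories. Forests use `mtry = floor(√D)` features
per split and out-of-bag (OOB) predictions for honest evaluation;
R²_adj = 1 − (1 − R²)(n − 1)/(n − D − 1). Model significance is assessed by
refitting against permuted targets; feature significance uses the Altmann
permutation scheme, p = (1 + #{null ≥ observed})/(1 + n_perm).

**Importance-measure choice:** the observed statistic defaults to
scikit-learn impurity importance (`importance_kind="impurity"`), with
out-of-sample permutation importance available via
`importance_kind="permutation"`. Within-tree OOB permutation importance (as
in the ranger R package) is not exposed by scikit-learn; the Altmann
construction is valid for any importance statistic because observed and null
values use the same one, and impurity importance makes the permutation loop
(which refits the forest per permutation and dominates cost) markedly
cheaper.

Predicted continuous slopes are mapped to classes by nearest component slope
(ties to the lower index); classification quality is reported as per-class
one-vs-rest accuracy (TP+TN)/N and a confusion matrix. Two OOB R² values on
independent cohorts are compared with a Fisher-Z test on √R².

## 6. Synthetic data generator (`trclust.synthetic`)

### What it emulates

- 7 latent response classes with ln-scale intercepts ≈ 3.05–3.30 and weekly
  slopes from −0.22 (fast responders, discharge around week 5) to −0.002
  (non-responders, never discharged by week 16), residual SD 0.12, mixing
  weights between 0.08 and 0.20; n = 1000 by default on the MARS design.
- **Discharge-driven dropout:** a patient's series ends after two consecutive
  scheduled visits with raw score < 10 from week 2 on — missingness is
  outcome-dependent, as in naturalistic inpatient data.
- **Accidental missingness:** 7.1% of weeks 1–6 visits are deleted at random
  (never baseline, never the discharge-defining visits).
- **Eligibility:** draws are resampled until baseline ≥ 14, mimicking an
  inclusion criterion rather than truncating the score distribution.
- **Baseline covariates:** 50 items (numerical/dichotomous/categorical) with
  realistic marginal means and SDs. Nine items are class-informative:
  class-specific shifts follow fixed profiles and are scaled so the
  population Cohen's f hits a target per item (e.g. neuroticism 0.355, harm
  avoidance 0.341, depression index 0.153) — calibration is exact by
  construction and verified by ANOVA in tests. HAM-D single items are
  generated label-independent (the study condition in which they add no
  predictive value over model 0).

`separated_spec(k_true, …)` builds smaller-variance, well-separated variants
(σ = 0.08, slope gaps several times the truncation-aware slope standard
error) for recovery and model-selection experiments; it was fixed before the
experiments were run, not tuned to their outcomes.

### What it does not emulate

- No within-patient autocorrelation beyond the class line (residuals are
  i.i.d.); no measurement-occasion effects or rater drift.
- Covariate effects are additive mean shifts only — no interactions,
  nonlinearity, or covariate-dependent slopes.
- Dropout other than discharge (e.g. deterioration-related) is absent.
- Class-conditional distributions are exactly Gaussian on the ln scale.

## 7. Numerical and design choices

- All randomness flows through `numpy.random.Generator`; multi-restart and
  multi-cohort sub-seeds come from `SeedSequence.spawn`, so every pipeline
  stage is byte-reproducible given (inputs, configuration, seed).
- E-step normalization uses max-shifted log-sum-exp; a patient whose density
  underflows under every component receives a uniform posterior with a
  warning instead of NaNs.
- Established libraries are used for standard steps (scipy for chi-square,
  F, normal and KS distributions; scikit-learn for forests; pandas/CSV/JSON
  for I/O); the grouped mixture-of-regressions EM and ICL selection — the
  core of the method — are implemented here, since generic Gaussian-mixture
  implementations cannot share a latent class across a patient's
  observations.
- Problem sizes in the test suite (restart counts, forest sizes, permutation
  counts) are scaled down from the operational defaults to keep the suite
  fast while still exercising every code path; the defaults themselves
  (200 restarts, 2000 trees, mtry = √D) are unchanged.

## 8. Limitations

- Linear class trajectories on the ln scale; curvature (early plateau,
  relapse) would require polynomial or spline class means.
- ICL with random-partition restarts can under-select K when classes overlap
  heavily; the selection experiments use separated classes to define a
  recoverable regime, and real-data analyses should inspect the full ICL
  profile rather than the minimizer alone.
- OOB R² with small forests is noisy and can be slightly pessimistic;
  adjusted R² can be negative for null models by construction.
- The chi-square homogeneity test assumes independent cohorts and adequate
  expected counts; very small classes should be pooled by the analyst.
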