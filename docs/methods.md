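# Methods

## The model

`firefit` fits a linear many-to-many regression between an n×5 block X of
physical-fitness measures and an n×7 block Y of task completion times by
partial least-squares (PLS). The working assumption is that a small number
h of latent fitness factors drive both blocks: subjects differ along a few
axes (aerobic capacity, muscular power, body composition), each measured
variable loads on those axes linearly, and task times are linear in the
axes plus noise. PLS estimates the axes directly from the X–Y
cross-covariance, which keeps the fit well-posed when n is small (20 in the
motivating design) and the predictors are strongly collinear — conditions
under which ordinary least-squares coefficients are unstable.

### Component extraction

Both blocks are autoscaled — each column centered and divided by its sample
standard deviation (ddof = 1). The variables span incomparable units (kg,
mL/kg/min, %, W, s), so covariance-scale PLS would let the largest-variance
columns dominate; autoscaling is the standard remedy and the package's
fixed choice.

From the current residual blocks E (starts at standardized X) and F
(standardized Y), one component is extracted at a time:

1. weight vector: w = dominant left singular vector of E′F, computed by
   exact SVD (equivalent to a fully converged NIPALS inner iteration). Its
   sign is fixed so the largest-magnitude entry is positive — the singular
   direction is only defined up to sign, and a deterministic convention
   makes serialized fits diffable.
2. scores: t = E w (a linear combination of the predictor columns);
   u = F β/‖β‖.
3. loadings: α = E′t/‖t‖², β = F′t/‖t‖² — least-squares regressions of each
   block on the score.
4. deflation: E ← E − t α′, F ← F − t β′.

Deflating **both** blocks by the t-based rank-one term is the standard
NIPALS/SIMCA convention and is the one consistent with estimating β by
regressing F on t; formulations that write the Y-block decomposition in
terms of u are not self-consistent with that estimator, and this package
does not use them.

Scores of successive components are mutually orthogonal; the accumulated
regression collapses to original-units coefficients B = D_x⁻¹ · W(A′W)⁻¹C′ ·
D_y (D = diagonal scale matrices, A and C the loading matrices) with
intercept b₀ = ȳ − x̄B. Component-wise and coefficient-form predictions
agree to round-off; both identities are asserted in the test suite at 1e-8.
The component count is capped at min(n − 1, m).

### Component selection (PRESS/Q²)

For h = 1, 2, …:

* PRESS(h): every row i is predicted by an h-component model fitted to the
  other n − 1 rows. Fold models re-estimate their centering and scaling on
  their own 19 rows; the left-out errors are divided by the **full-sample**
  response scales so that PRESS is commensurable with SS. Squared errors
  are summed per response, then over responses.
* SS(h): in-sample residual sum of squares of the h-component fit on all
  rows, same scale. SS(0) is the total centered sum of squares of
  standardized Y, i.e. p·(n − 1) — the natural h = 0 baseline required by
  the Q² ratio.
* Q²ₕ = 1 − PRESS(h)/SS(h−1). A component is retained while Q²ₕ ≥
  1 − 0.95² = 0.0975 (the conventional "a component must predict at least
  5% better than doing nothing" limit); extraction stops at the first
  failure, so the retained set is always a prefix.

Two guard rails: (i) if even the first component fails, a one-component
model is still returned with `significant=False` — downstream stages need a
model, and the flag preserves honesty; (ii) extraction stops when SS(h−1)
falls below 1e-12·SS(0), because on noise-free data the model is already
exact and Q² would be a ratio of round-off terms.

PRESS(h) ≥ SS(h) typically holds but is not guaranteed; violations are
recorded on the CV table (`press_ge_ss_violations`), not raised.

### Sensitivity analysis

From the per-predictor summary (mean, min, max, range) an 8-level grid is
built: level k of predictor j is x_min_j + c_k·x_dif_j with c ∈ (−0.2, 0,
0.2, 0.4, 0.6, 0.8, 1.0, 1.2). The two outer levels deliberately
extrapolate 20% beyond the observed range; a notice is logged rather than
refusing. Each predictor sweeps its grid while the others sit at their
means, and the fitted model predicts the seven task times. Since the model
is linear, every curve is exactly affine with step 0.2·x_dif_j·B[j,·] —
asserted to 1e-9 in the suite.

Trends are classified per (predictor, task): *negligible* when the curve's
total excursion is below `flat_tol` times the all-means baseline
prediction, else *increasing*/*decreasing* by slope sign. `flat_tol`
defaults to 0.02 (2%): "little change" is not a quantified notion in this
literature, and 2% of a task time is comfortably below between-subject
variation; the threshold is exposed as a parameter.

### Evaluation

`split_dataset` partitions subjects uniformly at random (seeded) with test
size round(n·fraction), minimum 1 — for n = 20 and fraction 0.2 that is 16
train / 4 test. `loo_report` scores leave-one-out predictions over the full
cohort and, when a split is requested, the refitted training model
in-sample and on the held-out rows.

The accuracy metric is a package choice: published figures of this kind
rarely define their "prediction accuracy", and without the raw data no
definition can be recovered. The default is

    accuracy_j = 100·(1 − meanᵢ |ŷᵢⱼ − yᵢⱼ| / yᵢⱼ),  floored at 0,

i.e. mean percentage closeness of predicted to observed times, averaged
over responses for the overall figure. Alternatives (100·(1 − NRMSE),
100·R²) sit behind the `metric` flag. Task times must be strictly positive
for the relative metrics to make sense, which the dataset contract already
enforces.

## The synthetic cohort generator

No raw measurements exist publicly, so the generator emulates the study
conditions: n = 20 subjects, latent rank 2, per-subject latent scores drawn
spherically standard normal, standardized blocks S P′ + ε and S Q′ + ε with
unit-norm loading rows and per-column noise sd 0.3 — a noise level at which
the Q² rule typically retains both factors. Each predictor column is then
mapped affinely onto the published cohort (min, max) — e.g. weight spans
exactly 56–90 kg — which makes summary tables deterministic while
preserving the linear latent structure. Response columns are mapped
affinely onto ±20% around per-task baseline times (25, 90, 15, 120, 180,
1500, 20 s — plausible magnitudes chosen once; the study published no
response summaries), guaranteeing strictly positive times.

The default loadings encode a general-fitness factor (raises VO₂max and
power, shortens all tasks) and a body-size factor (raises weight and body
fat, slows the climbing tasks, mildly speeds the loaded carries). They are
a modelling choice, not an estimate.

What the generator does **not** emulate: the study's real covariance
structure, measurement error of the individual instruments, any
non-linearity, and the actual response distributions. Passing tests
therefore demonstrate that the *procedure* is implemented correctly and
behaves as theory predicts on data satisfying its assumptions — not that
the original study's numbers are reproduced. In particular the study's
headline leave-one-out accuracies cannot be verified and are not asserted
anywhere; the suite instead pins properties with independent oracles
(ordinary least-squares at full rank, an external PLS implementation,
fold-by-fold PRESS loops, the generator's known coefficient map).

### Test-design notes

* *Coefficient recovery with noise* is checked with predictor noise absent
  and response noise 0.2 at n = 2000: with noisy predictors the
  least-squares map is attenuated relative to the generating map (classical
  errors-in-variables), so exact recovery is only a property of the
  noise-free-X regime. With unit-norm response loading rows, response noise
  shrinks standardized coefficients by 1/√(1 + sd²) ≈ 2% at sd 0.2, inside
  the 5% test tolerance.
* *Rank-l selection checks* use configurations whose factors have
  decreasing response strength (variance ratio 1 : 0.09 : 0.0225). With
  equal-strength factors the SIMCA stop rule can legitimately halt before
  rank l, because an h-component model's leave-one-out error still contains
  every unexplained factor; decreasing strengths give each successive
  component genuine incremental value, which is the regime the selection
  rule is designed for. The complementary property — selection never
  *exceeds* the true rank on noise-free data — is asserted over a spread of
  random configurations.

## Problem sizes

The suite and the acceptance script run the study-scale problem throughout:
n = 20 cohorts (n = 2000 only for the single coefficient-convergence
check), leave-one-out over all rows, 50 random instances for the
external-implementation comparison. The whole suite completes in a few
seconds.

## Known limitations

* Strictly linear model: no interactions, no curvature, no categorical
  predictors.
* No missing-data handling — validation rejects incomplete tables.
* Leave-one-out is the only cross-validation scheme (no k-fold or
  Monte-Carlo variants), matching the procedure being replicated.
* The accuracy percentages depend on the chosen metric; comparisons to
  figures computed under an unknown metric are indicative only.
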