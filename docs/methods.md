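# Methods

## Model

The package models weekly follow-up outcomes — pain intensity (0–10 NRS),
posture quality (0–10), and training duration (log-minutes) — over an
8-week program as a two-segment linear ("piecewise") trajectory with a
breakpoint at week *c*:

    y_ij = b0 + b_pre * w_pre_ij + b_post * w_post_ij
           + u0_i + u1_i * w_pre_ij + e_ij

with, for user *i* in week *w* (time origin at week 1, `t = w − 1`,
`c' = c − 1`):

    w_pre  = min(t, c')          w_post = max(t − c', 0)

so `w_pre + w_post = t` and the mean trajectory is continuous at the break.
`b0` is the expected outcome at week 1, `b_pre` the weekly change during
the initial training period, `b_post` the weekly change afterwards.
`(u0_i, u1_i)` is a user-level random intercept and random slope on the
first segment with unstructured 2×2 covariance; `e_ij` is iid Gaussian.
Setting the breakpoint at (or beyond) the last observed week makes
`w_post ≡ 0`, which is the single-slope linear comparator.

Mixed models are estimated by statsmodels' `MixedLM`. Maximum likelihood is
the default, because all model comparisons here are AIC comparisons across
different fixed-effect structures, for which REML likelihoods are not
comparable; REML remains available for variance estimation. The parameter
count entering `AIC = −2ℓ + 2p` is the number of fixed effects plus the
variance parameters (two SDs, one correlation and the residual SD when the
random slope is present; intercept SD and residual SD otherwise).

## Model-based tree

`fit_lmm_tree` grows a recursive partition over user-level moderators
(age, gender, BMI) in which each terminal node has its own
`(b0, b_pre, b_post)` while the random effects stay global. Estimation
alternates:

1. subtract the current random-effect predictions from the outcome;
2. grow a model-based tree on the adjusted outcome: each node fits
   `y* ~ 1 + w_pre + w_post` by least squares, tests parameter stability
   along every moderator, and splits where instability is significant;
3. refit the joint mixed model whose fixed effects are terminal-node
   indicators interacted with `(1, w_pre, w_post)`, with the global random
   intercept + slope;
4. repeat until the log-likelihood changes by less than `tol = 1e-4`
   (cap `max_iter = 100`; typical runs converge in 2–4 alternations).

Node coefficients, standard errors and Wald p-values reported for the final
tree all come from the joint mixed-model fit, so nodes are mutually
adjusted for the shared random effects. The Wald intervals are naive: no
adjustment for having selected the partition from the same data. Random
effects are never re-estimated within nodes — subgroups differ only in
fixed effects.

### Instability tests

Splitting decisions use score-based structural-change tests on the node
model's estimating-function contributions (`x_ij · r_ij`):

* numeric moderators: the sup-LM statistic, the maximum of
  `‖W(t)‖² / (t(1−t))` over the scaled cumulative score process, with 10%
  trimming and evaluation only at admissible cut points (boundaries between
  distinct moderator values);
* categorical moderators (binary only; gender here): a chi-square statistic
  aggregating squared within-category score sums, `k(C−1)` degrees of
  freedom;
* Bonferroni correction across the moderators testable at the node,
  family-wise level `alpha = 0.05`.

**Cluster aggregation.** Scores are summed within user before testing.
Moderators are constant within user and repeated measures of one user are
correlated even after subtracting BLUPs, so observation-level tests
overstate the evidence for splits by an order of magnitude (in our null
simulations they produced spurious splits in ~80% of cohorts; user-level
aggregation brings the family-wise false-split rate to the nominal ~5%).

**Null distribution.** The trimmed sup-LM statistic's null law (a
functional of a k-dimensional Brownian bridge) has no closed form. p-values
are interpolated from simulated quantile tables shipped with the package
(`data/suplm_quantiles.json`): 400,000 replicates of the limiting bridge
functional on a 1024-point grid anchor n = ∞, and exact finite-n statistic
distributions (100,000 replicates each at n ∈ {50, 100, 200, 400, 800,
1600}, simulated with the same whitening and trimming the test uses)
correct the moderate-sample calibration, interpolating linearly in 1/n.
Beyond the tabulated upper tail the p-value is extrapolated log-linearly.
Measured size at alpha = 0.05 is ≈0.05 for n between 100 and 500.

### Split search and prepruning

The split point on the selected moderator minimizes the sum of the two
children's least-squares residual sums of squares under the full node model
(not intercept-only), scanned exhaustively over midpoints of adjacent
distinct values via cumulative sufficient statistics; ties go to the
smaller threshold. Prepruning follows the study design: `minsplit` (default
90 for pain/posture, 100 for training duration) counts rows (observations,
not users) and must be met by the parent to attempt a split and by both
children; `maxdepth` caps the root-to-leaf depth and is tuned over 2–5 by
AIC. A node with a rank-deficient design is forced terminal with a logged
warning rather than an error.

## Selection and evaluation

* Breakpoint: candidates at weeks 3 and 4 plus the single-slope model,
  compared by ML AIC with the same random structure (the linear model's
  random slope rides on its only time covariate). Ties break toward fewer
  parameters. If the linear model wins, it is reported as the selection but
  the tree stage uses the best piecewise candidate.
* Train/test: user-disjoint 80/20 split, `round(0.2 · n_users)` test users.
* Cross-validation: user-disjoint 5-fold partition of the training set;
  fold sizes differ by at most one user.
* RMSE: training error uses full-model predictions (including BLUPs); test
  and validation errors use fixed effects only, since BLUPs are undefined
  for users absent from training — the expected test > train gap therefore
  contains the between-user variance, not only overfitting.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
data set: complete 8-week panels; subgroup-specific piecewise fixed effects
planted through interval rules on age/BMI and gender categories (rules must
tile the moderator space — checked at generation); bivariate Gaussian
random effects; Gaussian residuals. Moderator marginals default to
age ~ truncated Normal(43.8, 15.8²) on [15, 94], BMI ~ truncated
Normal(24.5, 5.0²) on [11, 55], and 60% women. Training duration is
generated on the log scale and exponentiated, giving right-skewed weekly
minutes. Pain/posture values are continuous and unbounded by default;
clipping to [0, 10] is available but off, because clipping biases the
trajectory parameters the tests try to recover. The inclusion screen
(first-assessment pain strictly > 4, at least 2 ratings, at least 8 weeks
with strictly more than 360 training minutes) is implemented as a separate
filter with per-rule exclusion counts. An optional fraction of users with
entirely missing self-reports mimics device users who never rate.

What the generator does **not** emulate: dropout and informative
missingness, digit preference and floor/ceiling effects in self-reports,
within-week usage patterns, non-Gaussian residuals, and any true
moderator–trajectory relationship beyond threshold rules. Passing
recovery tests therefore shows the estimator works when its assumptions
hold, not that those assumptions hold in field data.

The `study` module plants the published subgroup structure as generator
defaults: printed node coefficients are used verbatim (e.g. week-1 levels
of ~280/462/470 minutes and a +0.108 log-slope for the over-37 group in
training duration; pain intercepts 5.173/6.156/5.383/5.260), slopes
reported only as non-significant are planted at zero, and variance
components — which the source figures do not print — are set once to
realistic magnitudes for these scales (residual SD 1.0 on log-minutes, 1.6
on the 0–10 scales; intercept SD 0.9–1.2; slope SD 0.12–0.15).

## Numerical choices and degenerate inputs

* Mixed-model optimizer: L-BFGS with one derivative-free (Powell) restart
  on failure; non-convergence is reported via `converged=False`, never
  raised, and non-convergent candidates are excluded from AIC argmins with
  a warning.
* Zero-variance limit: when variances are forced to zero the fit is
  computed directly by least squares (the exact limit of the mixed
  likelihood) rather than through the optimizer.
* Rank checks use pivoted QR; the error names the collinear columns.
* Median/IQR use linear interpolation between order statistics. The
  Wilcoxon rank-sum comparison uses exact enumeration for tie-free samples
  up to n = 50 per group, otherwise the normal approximation with
  continuity and tie corrections; identical groups give p = 1.
* Unseen users predict with BLUP = 0 (the prior mean) in every predictor.
* Moderators must be user-constant (error otherwise); categorical
  moderators with more than two levels are rejected as unsupported.

## Problem sizes

Simulation-based tests and the acceptance script use cohorts of 150–1000
users (the selection/calibration suites use 200–500 users with 20–200
replicates, the end-to-end pipeline runs 1000 users). These sizes were
chosen so every simulated check has clear statistical resolution while a
full run of the suite stays in the minutes range on one CPU.

## Known limitations

* Inference in terminal nodes ignores the selection of the partition;
  intervals are anti-conservative in the usual post-selection sense.
* The alternation is monitored by log-likelihood convergence only; the
  partition at the final iteration is reported even if it still differs
  from the penultimate one (flagged via `converged`).
* Only two-level categorical moderators are supported.
* The sup-LM tables cover node models with up to 4 parameters and 10%
  trimming; other trimming values raise an error rather than silently
  using a mismatched table.
* Breakpoints are fixed candidates, never estimated freely; splines and
  more than two segments are out of scope.
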