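# Methods

## Instrument and scoring

The bundled schema has 24 food-item questions and 11 nutrition goals.  A
goal's quality score is the **unweighted sum** of its contributing
questions' portions/day.  Summing (rather than averaging or rescaling)
keeps scores, thresholds and prediction errors on a single portions-per-day
scale.  The question→goal mapping, each goal's direction (*at least* /
*at most*) and its threshold are shipped as an editable YAML/JSON schema;
the default thresholds are **placeholder conventions**, not
dietary-guideline values, and should be replaced for any real deployment.
One question ("other oils/butter") feeds no goal because its healthy
direction is ambiguous.  In the default instrument a question contributes
to at most one goal, and several goals depend on a single question — the
instrument is deliberately simple, which bounds how much any selection
method can improve on a good baseline.

## Preprocessing

Features and targets are min–max scaled to [0, 1].  Scaling parameters are
fit **on the training rows only** (the 3:1 split); fitting on all rows is
available via `scaling_scope="all"` for comparison.  Constant columns are
mapped to 0 forward and to their constant on the inverse — the scaling
formula itself divides by zero there, and a constant column carries no
information, so totality is preferred.  Test-set values may leave [0, 1]
and are *not* clipped; predictions and truths are inverse-transformed to
portions/day before errors are computed, so reported errors are
interpretable against the thresholds.

## Regression and feature importance

The predictor is ordinary least squares per target over one shared feature
set (multi-target linear regression).  The relationship between answers and
scores is linear by construction, and flexible learners gain nothing here
while risking overfit.  The fit is the minimum-norm solution, so duplicate
or zero columns are handled silently; with a zero (scaled-constant) column
the minimum-norm coefficient is exactly zero, which is why constant
questions get zero importance.

A question's importance is the **fold-averaged mean absolute coefficient**:
5 seeded folds partition the training rows; on each fold's training part
the model is fitted on all 24 questions; the fold importance of question
*j* is the mean of |coef(t, j)| over targets *t*; the final importance
averages the folds.  On min–max-scaled data absolute coefficients are
comparable across questions and targets.  Importance is linear in the
targets, which is exactly the lever the personalised weighting uses.  Ties
are broken by schema question order (stable, documented).  The importance
function is isolated so alternatives (e.g. univariate correlations) can be
swapped in.

## Personalised selection

Step 1 runs the static pipeline on the activated goals and predicts their
scaled scores for the evaluation rows.  Step 2 computes each goal's
violation distance `max((y_pred − y_opt)·y_adj, 0)` — thresholds are mapped
through the *target* scaling so `y_pred` and `y_opt` are commensurable —
turns distances into weights, multiplies the training target columns by the
weights, recomputes the importance and reselects the top *n*.

Design choices:

- **Divide-by-max, not min–max, for the weights.**  Min–max would force the
  least-violated goal's weight to 0 and erase it from the regression; with
  divide-by-max the most violated goal gets weight 1 while satisfied goals
  keep a small weight.  The alternative is available via
  `weight_scaling="minmax"`.
- **Weight floor ε = 0.05** (configurable): a zero weight would zero a
  target column, making its coefficients — and its reported error —
  meaningless.
- **No violation ⇒ uniform weights 1**, so the personalised arm reduces
  exactly to the static arm; likewise with a single activated goal (its
  weight is 1 whatever its distance).
- **Population vs user mode.**  The experiments compute weights from the
  *mean* predicted score of the held-out rows (population mode); an app
  would use one user's own previous answers (`mode="user"`), which the same
  function supports.

Because per-target OLS is separable, reweighting targets changes no single
goal's fit: the weights act **only** through the selection of questions.
This makes the mechanism transparent — the personalised arm wins on a
violated goal precisely when the reweighted importance pulls that goal's
questions into the grid.

## Synthetic populations

The generator stands in for the non-redistributable questionnaire datasets
such studies use.  Each user is drawn from a three-profile mixture
(weights 0.40 / 0.35 / 0.25):

- **prudent** — meets every default threshold at its mean vector;
- **sweet_tooth** — strongly over-reaches sugar (5.0 vs 2.0 portions/day at
  the mean), sweets/snacks and sweet drinks;
- **low_veg** — under-reaches the *at least* goals (fruit & vegetables,
  water, dried fruit, oil).

Per-question answers are multivariate normal with means from the profile,
standard deviation = mean × coefficient of variation (0.4 throughout, a
typical day-to-day spread for food-frequency data), block correlation
within the carbohydrate group (ρ = 0.6), the sweets group (ρ = 0.5) and
fruit/vegetables (ρ = 0.5), truncated at zero.  Truncation is simple and
monotone; it biases means upward for low-mean items (≲ 0.1% at cv = 0.4),
which the convergence test accounts for.  One seed drives a dedicated
generator; there is **no prefix property** (changing `n_users` changes all
rows).

What the generator does *not* emulate: real marginal distributions
(zero-inflation, heaping at integer portions), reporting error between
answers and true intake, and any nonlinearity between answers and scores —
scores are exact sums of answers, so goals whose questions are all selected
are predicted essentially exactly.  Passing tests therefore demonstrate the
selection machinery, not clinical validity on real populations.

## Experiments

A sweep is a full factorial over arms × grid sizes × activated-goal
combinations × seeds.  One experiment seed derives four independent
sub-seeds (generator, split, CV folds, random arm) via seed-sequence
spawning, so all arms see identical data, splits and folds.  Errors are
MAE in portions/day (RMSE via `error_metric="rmse"`), reported for
**activated goals only** — the non-activated goals are not modelled.
Failing cells become `status="failed"` records rather than aborting a
sweep.

There are 2^11 − 1 − 11 = **2036** activated-goal combinations with at
least two goals.  (Printed counts of 2037 for this quantity include the
empty set: 2^11 − 11.)  The full factorial is feasible but slow in routine
runs, so the default configuration samples 60 combinations stratified by
set size; `stratified_combination_panel` provides a deterministic balanced
alternative — contiguous cyclic blocks of the goal order at evenly spaced
offsets — used for trend analyses because it equalises goal coverage
within each set size.  With few combinations per size, *which* goals land
in a random sample dominates the per-size mean (per-goal error scales
differ several-fold), and the balanced panel removes that composition
variance.

Trend analyses at the default study scale (1000 users, 10 seeds, grid
sizes {4, 6, 9, 12}, the 20-combination balanced panel, ~13 s on one CPU)
check three directional conclusions: mean error is non-increasing in the
number of questions shown in every arm; mean error of the
*feature-selection* arms is non-decreasing in the number of activated goals
(the random baseline is excluded from this monotonicity check because its
expected per-goal error is constant in the set size — its selection ignores
the targets and per-target fits are independent, so its per-size means are
flat plus noise); and the personalised arm predicts the maximum-weight goal
at least as well as the static arm in ≥ 70% of cells (observed: ≈ 99%).

## Numerical notes and limitations

- Minimum-norm OLS via LAPACK `gelsd`; oracle tests compare against an
  independent normal-equations/pseudo-inverse solution at 1e−8.
- Min–max round trips are exact to 1e−10; degenerate columns exactly.
- The 3:1 split takes the first ⌈0.75 n⌉ rows of a seeded permutation and
  requires n ≥ 8 (below that, 5-fold CV on the training part is
  meaningless).
- Weights computed in population mode use predictions on the held-out rows
  (the predictions the static arm already produces); the selected subset is
  then refit on training rows only.  In user mode no such reuse occurs.
- Single-run results at small `n_users` are noisy; directional claims are
  only asserted as means over ≥ 10 seeds.
- Statistical significance between arms is not assessed, and longitudinal
  (repeated questionnaire) behaviour — where weights would be updated from
  a user's actual previous round — is out of scope.
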