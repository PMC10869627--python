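# Methods

## Model

Each patient's week `t` carries a hidden mental state
`X_t ∈ {S, U}` (stable / unstable) and an observed crisis indicator
`Y_t ∈ {0, 1}`. The state evolves as a first-order Markov chain with
`P(U|S) = q` and `P(U|U) = r`; crises are emitted only in U, with
probability `p` per week. The model's assumptions, in order of
strength: exactly two states; first-order Markov dynamics; zero crisis
probability in S; `p`, `q`, `r` constant over time. Under these
assumptions a crisis observed at week `t` certifies `X_t = U`, which is
what makes the post-crisis prediction problem tractable in closed form.

## Closed-form risk and the Bayes filter

Anchored at an observed state at week 0 followed by `t−1` crisis-free
weeks, the predictive risk `P(Y_t = 1 | history)` obeys a scalar
Riccati difference equation. Writing `D = 1 − pr + r − q` and
`R = (r−q)(1−p)/D²`, the fixed points are the roots
`y± = (1 ± √(1−4R))/2` of `y² − y + R`, and

    risk(t) = 1 − D · [(y0−y−)·y₊^{t+1} − (y₊−y0)·y₋^{t+1}]
                    / [(y0−y−)·y₊^t − (y₊−y0)·y₋^t],

with `y0 = R(2w − 1)/(2R + w − 1)` and `w = (1−pr)/D` for a U anchor,
`(1−pq)/D` for an S anchor. As `t → ∞` the risk converges
geometrically to `1 − D·y₊`. Given the anchoring state, the week-0
crisis indicator adds no information, so it enters only as a
consistency check (a crisis in S is contradictory).

The same quantity is computed for arbitrary observation histories by
an exact recursive Bayes filter over `P(X_t = U | history)`:
transition (`π′ = πr + (1−π)q`), prediction (`risk = pπ′`), update
(a crisis sets the posterior to 1; a quiet week multiplies by
`(1−p)/(1−pπ′)`). The filter is the semantic ground truth; the closed
form is an optimisation verified against it to 1e−10 over the
simulator's whole parameter range. Prediction falls back to the filter
whenever the closed form's preconditions fail (`p ≥ 1 − 1e−9`,
`|q − r| ≤ 1e−9`, a vanishing denominator, or a negative discriminant
— the last provably never occurs for `r > q` in the supported ranges,
but the guard stays). For a patient with no observed anchor the filter
starts from the stationary law `π_U = q/(1+q−r)` of the state chain.

Numerical choices: the closed form divides both Riccati sums by
`y₊^t` so large horizons neither overflow nor cancel; `y₋` may be
negative (when `r < q`), so integer exponents are used. With
`p = r = 1` a crisis-free week after a crisis has probability zero;
the scalar filter raises on such impossible histories, the vectorised
policy filter applies the analytic limit (posterior → 0), and the
monitoring plan treats the patient as always-monitored.

## Estimation

Baum-Welch (EM) with per-step normalised forward/backward values
(scaling constants accumulated in log space; raw recursions underflow
near T ≈ 260). The M-step is expectation counting: `q̂` = expected S→U
transitions over expected weeks in S, `r̂` = expected U→U transitions
over expected weeks in U (transition sums run over `t = 0..T−1`), and
`p̂` = expected crisis-weeks in U over expected weeks in U, summed over
every week including the last — the exact maximiser of the EM
surrogate's emission term. With that exact M-step the log-likelihood
is non-decreasing at every iteration, which the test suite asserts to
1e−8.

The initial-state distribution is not a free parameter (the model is
deliberately three-dimensional). By default the forward recursion
starts from a fixed uninformative `P(X_0 = U) = 0.5`, held constant
during the run so the exact-EM monotonicity guarantee applies; one
week of prior cannot move a 200-week fit. A variant that re-ties the
prior to the stationary law of the current `(q, r)` each iteration is
available (`FitConfig(init_prior_U=None)`), but it turns the update
into a generalised-EM step whose log-likelihood can dip by ~1e−3 and
is therefore not the default.

Defaults: tolerance 1e−5 on the log-likelihood change, 100 iterations
(pooled) or 1000 (per-patient at simulation scale), random restarts
drawn uniformly from (0.02, 0.98)³ with `q = r` rejected, best restart
by highest log-likelihood with ties to the lowest index. Boundary
handling: estimates clamp to [0, 1]; a zero expected-occupancy
denominator freezes that parameter and flags the fit unidentifiable,
as do all-zero sequences (a never-crisis patient carries no
information about `p` or `r`). If a fitted `|q̂ − r̂| < 1e−6, prediction
simply routes through the filter; the estimate is not distorted to
satisfy the closed form's precondition.

A vectorised engine runs the identical EM for thousands of sequences
(and all their restarts) simultaneously as (B, T) array recursions,
with converged sequences dropping out of the active set; tests pin it
to the scalar reference path exactly. Pooled estimation sums the
expectation counts over patients (their observations are independent)
and reduces to the single-patient fit for a cohort of one.

## Monitoring policy

A patient-week is flagged when the predicted risk exceeds τ
(default 0.35). `weeks_to_stable` anchors the risk curve at an
observed crisis and reports the last week within a 104-week horizon
whose risk exceeds τ (the curve need not be monotone in every
parameter corner); `never` if no week does, `always` if the asymptotic
risk itself is at or above τ — a horizon-free decision via the closed
form limit. The crisis week itself is not counted: a plan of 1 means
"monitor the week after the crisis, deem stable from the second week".
Patients with under `min_history_weeks` (default 13 ≈ three months) of
history receive the pooled average-patient parameters; "less than" is
strict, so exactly 13 weeks earns an individual fit.

## Synthetic cohorts

The simulator emulates a heterogeneous hospital: per-patient
`(p, q, r)` drawn from lognormal distributions with shape parameters
1.2 / 1.0 / 0.3, mapped into (0.02, 0.98) / (0.02, 0.5) / (0.02, 0.98),
300 of 3,000 patients reassigned `r = 0` (isolated-crisis patients,
keeping their sampled `p` and `q`), trajectories of 260 weeks (five
years) with the first 208 used for estimation and the last 52 for
policy evaluation, and initial states drawn from each patient's
stationary law so the panel has no start-up transient.

The lognormal-to-interval mapping is the one genuinely open design
choice, and every cohort-level property inherits it, so each
parameter's map is anchored to a documented feature of the cohort
being emulated rather than chosen freely:

- `p`: reflected batch min-max (largest draw → 0.02, smallest → 0.98).
  This makes `p` very skewed towards 1 (median ≈ 0.97) with a
  negligible low tail, matching the fitted-parameter distributions the
  model is meant to resemble, and introduces no free constant.
- `r`: scaled by 0.7 and clipped into the interval, putting ~85% of
  the nonzero mass above 0.5 and a minority of chronic patients at the
  upper bound.
- `q`: scaled by 0.033 and clipped; the factor is calibrated once (by
  root-finding across seeds, then frozen) so the cohort's mean weekly
  crisis prevalence is ~20% of patients, the documented activity level
  of the simulated hospital.

What the generator does not emulate: admissions and discharges
(trajectories are complete panels — no late-entering or censored
patients), diagnosis mixtures, time-varying emission probabilities, or
any within-patient nonstationarity. Passing tests on these cohorts
therefore demonstrate correctness of estimation and policy *under the
model's own assumptions*, not performance on real hospital data.

## Evaluation

The unit of analysis is the patient-week. Flags are crossed with
observed crises into a confusion matrix; precision, recall
(sensitivity), specificity, false-positive rate and F1 follow the
standard definitions, with zero-denominator rates reported as NaN with
a warning. With simulation ground truth, occupancy metrics report the
share of flagged weeks spent in U, the share of "deemed stable" weeks
(the first unflagged week closing each post-crisis episode; repeated
crises before the policy stops flagging extend the same episode) in U,
and the share of the four weeks after them in U. Monitoring plans are
histogrammed over {never, 1, 2, 3+, always}.

## Problem sizes and reproducibility

The acceptance script regenerates the full experiment — 3,000 patients,
260 weeks, per-patient EM (tolerance 1e−5, up to 1,000 iterations, a
single run per patient, which is how the simulation fits are described
and is consistent with their ~98.5% convergence rate), τ = 0.35 —
in well under a minute on one CPU thanks to the vectorised engine. The
test suite exercises the same pipeline at 300 patients (with the
forced-`r = 0` group scaled in proportion) and proportionally wider
tolerance bands. All randomness flows from explicit seeds through
spawned child sequences, so every figure is reproducible bit-for-bit
from a single integer.

## Known limitations

- Per-patient maximum likelihood on four years of weekly binary data
  is intrinsically noisy for quiet patients: below roughly 20 observed
  crises the likelihood surface flattens and sometimes genuinely
  prefers a degenerate low-`p` / high-`q` explanation over the
  generating triple (the fitted log-likelihood exceeds the truth's, so
  this is the estimator's behaviour, not an optimisation failure).
  Cohort-level recovery error is dominated by this data-sparse tail.
- The threshold convention is strict (`risk > τ` flags; a limit
  exactly at τ reads as always-monitored); values exactly at τ are a
  measure-zero corner and the choice is documented rather than load-
  bearing.
- Extensions the model deliberately excludes: more than two states,
  higher-order memory, time-varying `p`, and the incorporation of
  clinician-visit observations beyond a known state at the anchor
  week.
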