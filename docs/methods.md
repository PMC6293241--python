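# Methods

## The estimand: causal excursion effects

At each decision point t of a micro-randomized trial, an available user
(availability indicator Iₜ = 1) is randomized between push (Aₜ = 1) and
no push (Aₜ = 0) with probability pₜ. The proximal outcome Y_{t+1} is
binary: did the user complete the app's self-monitoring ("charting")
within 24 hours of the decision point. The causal excursion effect at t
contrasts pushing now (and then following the trial's protocol, which by
the design's wait rules sends no further push within 24 hours) against
not pushing now or within 24 hours, averaged over available person-time.
On the risk-ratio scale, given moderators f(Sₜ),

    log RR(t) = f(Sₜ)ᵀ β .

The marginal effect is the intercept-only case; effect modification by
week-in-study, weekday/weekend, or time-of-day slot enters through f.

## Estimation

β is estimated jointly with a working log-linear nuisance model
exp(g(Sₜ)ᵀ α) for the untreated outcome probability by solving

    0 = Σ_users Σ_t Iₜ Wₜ [ e^(−Aₜ fₜᵀβ) Y_{t+1} − e^(gₜᵀα) ] · ( gₜ ; (Aₜ − p̃ₜ) fₜ ),

where Wₜ = (p̃ₜ/pₜ)^{Aₜ} ((1−p̃ₜ)/(1−pₜ))^{1−Aₜ} and p̃ₜ is a reference
probability in (0, 1). Two properties drive the design:

- **Blipping down.** e^(−Aₜfₜᵀβ) removes the treatment effect from
  treated outcomes, so at the true β both arms have the same conditional
  mean and the residual is centered regardless of α.
- **Centering.** Because Aₜ is randomized with known probability,
  E[(Aₜ − p̃ₜ) h(Hₜ)] = 0 for any history function h when p̃ₜ = pₜ (and
  the weights Wₜ restore this for any fixed p̃ₜ). Hence the β-block of
  the estimating function has mean zero at the truth *even when the
  control model gᵀα is wrong* — misspecified nuisance models cost
  efficiency, never consistency. The test suite verifies this directly
  by planting a weekend uplift hidden from the analysis controls.

The solver is Newton–Raphson with the analytic Jacobian, step-halving
line search, tolerance ‖U‖∞ < 1e−8 on the per-user-mean estimating
function, and at most 100 iterations. α starts at the log of the
untreated outcome rate (intercept) and zeros; β starts at zero. The fit
is deterministic given the data. Degenerate inputs fail loudly: an arm
with all-zero outcomes raises a separation error, a constant model
column is named in the error, and non-finite exponentials report the
offending row.

Two risk sets are supported. The default restricts to considered
decision points, where the recorded randomization probability (0.5)
applies. The alternative (`mode="available"`) uses all available
person-slots, treating not-yet-considered slots as untreated with
pₜ = 0.5/(remaining open slots) — the probability implied by the
sequential uniform slot selection. Which risk set the original analysis
used is not determinable from the published description; both are
first-class and the restricted one is the default because the stated
randomization probability applies to it exactly.

## Inference

Variance is the user-clustered sandwich V = B⁻¹ M B⁻ᵀ / n, with B the
Jacobian of the mean estimating function and M the empirical second
moment of per-user score contributions. This is valid under arbitrary
within-person correlation of the binary outcomes over time; users are
the independent units. A Mancl–DeRouen-type leverage correction
(inflating each user's score by (I − Jᵤ B_tot⁻¹)⁻¹) is available behind
a flag and off by default; at the trial's scale (hundreds to thousands
of users) the uncorrected sandwich already attains near-nominal
coverage.

Hypothesis tests are Wald chi-square tests of Lβ = 0 with df = rank(L).
Confidence intervals are normal-theory on the log scale and
exponentiated, hence log-symmetric (ci_low · ci_high = exp(2 fᵀβ̂)) and
asymmetric on the risk-ratio scale, matching how such intervals are
conventionally reported. Exploratory time-of-day curves carry pointwise
90% intervals and deliberately no p-values.

## Trial design engine

- **Slots.** Six per day at 8.5, 12.5, 17.5, 18.5, 19.5, 20.5 hours; on
  weekends all slots before noon are closed (default: only the 8:30
  slot). Day 1's weekday is configurable (default Monday).
- **Availability.** A user-day is eligible when notifications are on and
  the days since the last decision reach the wait imposed by the current
  inactivity bucket: [0,2)→3, [2,10)→2, [10,30)→6, [30,∞)→15 days. Users
  who have never charted count inactivity as days since enrollment, and
  users with no prior decision are immediately eligible. The first-days
  behavior needs no extra rule; the <2-day bucket covers it.
- **Consideration.** Exactly one slot of an eligible day is considered,
  drawn uniformly among the day's open slots (equivalently, advancing
  past each slot with the complementary sequential probability). Slots
  before the considered one count as available person-time; once a slot
  is considered the user is unavailable for the rest of the day. Whether
  the deployed system could end an eligible day with no consideration is
  unknowable from the outside; exactly-one is fixed here because it
  matches equal marginal selection probabilities.
- **Spacing.** The minimum wait of 2 days guarantees no two decisions
  fall within 24 hours of each other, which is what makes the 24-hour
  proximal window a clean excursion contrast.

## Synthetic data-generating process

Outcome probabilities follow
min(cap, exp(gₜᵀα* + b_u + Aₜ fₜᵀβ*)) with per-user intercepts
b_u ~ N(0, user_sd²) inducing within-person correlation (user_sd = 0.25
by default) and covariate feedback through days-since-chart. Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| α*_intercept | log 0.25 | untreated daily chart probability ≈ 0.25 (a free simulation parameter; no published base rate exists) |
| α*_week | −0.005 | slow disengagement drift per week |
| α*_days-since-chart | −0.03 | per-day decay of re-engagement (covariate capped at 30 days) |
| α*_pushed, α*_success-ratio, α*_charted-10 | −0.15, 0.30, 0.15 | mild, plausible history dependence |
| β* | 0.04 | planted log risk ratio of a push |
| prob_cap | 0.95 | truncates the log-linear mean away from 1 |
| user_sd | 0.25 | heterogeneity scale |

With these defaults, uncapped probabilities stay below the cap in
essentially all person-time (the cap needs a ≈3.7σ user intercept to
bind), so the planted risk ratio is preserved where the estimator looks;
and the availability fraction lands at ≈20% of person-slots without any
tuning, emerging from the wait rules plus the chart dynamics.

**Chart mechanics.** At most one chart event per day. On a day with a
considered decision the chart is the decision's outcome draw, placed
uniformly inside that slot's 24-hour window (possibly the next calendar
day); spontaneous charting at the untreated rate occurs only on days
with no decision today or yesterday. Consequence: the recorded 24-hour
outcome at a considered slot is *exactly* the model's Bernoulli draw —
no other event can enter its window — so empirical risk ratios in
generated data converge to exp(fᵀβ*) by construction. The cost is a mild
stylization: users never chart in the hours before a same-day decision,
and post-decision quiet days are quieter than real behavior. Covariates
are computed strictly from the past (a push joins the success-ratio
denominator only after its full window has elapsed); the vectorized
simulator's columns are cross-checked in the tests against an
independent per-user reference derivation.

What the generator does **not** emulate: staggered enrollment, message
content and tailoring (only send/not-send is modeled), demographic
moderation (traits are fixture dressing), mid-study notification
disabling (supported as a configuration switch, off by default), and
real-world outcome misclassification. Passing tests therefore establish
the estimator's properties under a faithful model of the *design*, not
claims about any particular user population.

## Replication experiments and problem sizes

`recovery_experiment` runs simulate → fit → test over independent
replicates seeded from a single spawning sequence, and reports bias,
RMSE, coverage and rejection rates. The shipped experiments use cohorts
of 500 users over the full 89-day design — 200 replicates for recovery
and robustness, 500 for type-I error and coverage — sizes at which
Monte-Carlo error on a coverage estimate is about ±1 percentage point
and a full experiment completes in well under a minute per hundred
replicates on one CPU. Replicate failures are recorded and reported,
never silently dropped.

## Known limitations

- The log link can in principle drive fitted probabilities above 1; the
  estimator inherits this from the risk-ratio estimand and no constraint
  is imposed on ĝᵀα̂.
- The "available" risk-set mode derives slot-selection probabilities
  from the configured schedule; if records came from a different
  schedule than configured, those probabilities would be wrong.
- Small cohorts or short studies can make history covariates degenerate
  (e.g. nobody reaches 10 charts); the fit refuses such columns rather
  than guessing.
- The published per-coefficient results of the motivating study derive
  from a proprietary dataset and are not reproducible here; published
  coefficients are used only as planted truths and transform inputs.
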