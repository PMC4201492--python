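# Methods

## The dynamical model

A person's state is one continuous variable *M* (mood).  The
deterministic drift is the canonical cubic with roots *b* < *c* < *d* and
leading coefficient −*a* (*a* > 0),

    f(M) = −a (M − b)(M − c)(M − d) + I,

the unique degree-3 polynomial with zeros at the three named fix points
in which *b* and *d* are stable and *c* is unstable.  *I* is a constant
external input that tilts the double well.  Integration is explicit
Euler–Maruyama,

    M(t+dt) = M(t) + dt·f(M(t)) + σ·sqrt(dt)·z,   z ~ N(0, 1),

one independent draw per step, so the diffusion per unit time is
independent of the step size.

**Time units.**  Rates (*a*, *I*, σ²) are per *year*; clinical
bookkeeping (episode thresholds, day indices, durations) is in days.
This split is deliberate and load-bearing.  With the shipped parameter
sets, the two wells differ strongly in depth (for the low-risk set the
barrier out of the healthy well is ~3.5× the barrier out of the
symptomatic well).  If the drift were interpreted per day, any noise
level large enough to produce a realistic lifetime occurrence rate would
empty the symptomatic well within a few days, so essentially no
symptomatic period would reach the 14-day episode criterion — detected
lifetime occurrence saturates near 1% for every σ.  With year-scale
rates, well sojourns last months to years while 14 days is a small
fraction of the relaxation timescale, and a single noise amplitude
simultaneously yields a ~13% lifetime occurrence rate for the low-risk
population, near-certain occurrence with chronic episodes for the
high-risk population, and a ~20% occurrence rate for the homogeneous
single-population parameter set.  We therefore define the dynamics on
the year timescale and sample the trajectory once per calendar day.

**Integration step.**  `dt = 1/1460 y` (4 Euler steps per day).  The
fastest local relaxation rate among the shipped parameter sets is
a(d−b)(d−c) ≈ 189/y, so dt·|f′| ≈ 0.13, comfortably inside the explicit
Euler stability bound dt < 2/(a(d−b)(d−c)) that the parameter validator
enforces, and small enough that discretization inflates the stationary
variance near the fix points by under 7% (the residual is absorbed by
the noise calibration below).  No implicit or adaptive scheme is used.

**Noise calibration.**  σ is the one parameter the underlying studies do
not print.  It is fixed once by monotone bisection on the simulated
70-year occurrence rate of the low-risk parameter set
(a = 5, b = −2.85, c = 0.175, d = 5, I = 0.02, M0 = d), targeting
OR = 13%.  The result, σ = 10.55 mood units·y^(−1/2), ships as
`DEFAULT_SIGMA` and is used by all presets.  Nothing else was tuned: the
high-risk penetrance (~99%), the mixture occurrence rate (~20%), the
first recurrence rate (~38%), the bimodal episode-count distribution and
the long-tailed episode durations all follow from the printed parameter
sets at this single σ.

**Divergence guard.**  A trajectory whose |M| exceeds 100·max(|b|, |d|)
aborts with an error naming the offending step.  Under the shipped
parameters this indicates a mis-configured (too large) σ or dt, not a
plausible sample path.

**Daily signs.**  Day *k* is symptomatic iff the mood sampled at the end
of day *k* is strictly negative; an exact zero counts as asymptomatic
(the symptomatic state is defined by M < 0).  End-of-day sampling is the
simplest deterministic contract; the state machine consumes only
day-resolution signs.

## The disease-state machine

Nine states: NULL, DEPRESSIVE_EPISODE, REBOUND_DE, REMISSION,
INTERRUPTED_REMISSION, RECOVERY, INTERRUPTED_RECOVERY, RELAPSE,
REBOUND_RELAPSE; the four without prefix (plus DEPRESSIVE_EPISODE) are
clinically relevant, the rest absorb short interruptions.  Transitions
happen only when the daily sign changes, based on the length of the
completed run:

* NULL → DEPRESSIVE_EPISODE on ≥ 14 consecutive symptomatic days;
  shorter symptomatic runs (and any asymptomatic run) leave NULL
  unchanged and keep the NULL label (no auxiliary state is defined for
  them).
* Inside an episode, an asymptomatic run < 14 d is a rebound and extends
  the episode; ≥ 14 d ends the episode and starts remission.
* Inside remission, a symptomatic run < 14 d is an interruption and is
  absorbed; ≥ 14 d is a relapse (a new episode).  When the cumulative
  span of the remission period — asymptomatic runs *plus* absorbed
  interruptions — reaches 180 days, the whole period is retroactively
  relabeled recovery from its onset ("change previous state").
* Inside recovery, a symptomatic run ≥ 14 d is a recurrence: a new
  depressive episode.  A relapse that itself remits returns to
  remission; a further qualifying symptomatic run before recovery is
  another relapse.

The 14-day and 180-day thresholds are named constants
(`DEFAULT_EPISODE_THRESHOLD`, `DEFAULT_RECOVERY_SPAN`); "6 months" is
taken as 180 days.  An unterminated trailing run keeps its in-progress
label, and a trailing symptomatic run ≥ 14 d counts as an episode.
Episode durations run from onset to the start of the qualifying
asymptomatic run (or the end of the timeline), so rebounds are included
— the 28/5/27 worked example is one 60-day episode.

**Episode counting.**  `count_episodes` defaults to `all_episodes`
(every depressive-episode and relapse onset increments NDE; a relapse
satisfies the full syndromal criteria).  The stricter
`post_recovery_only` mode — only the first episode and episodes entered
from recovery — is exposed because the usual definition of *recurrence*
requires a preceding recovery.  All shipped statistics use the default.

The test suite checks the machine against an independently written
day-by-day rule interpreter on 10,000 fuzzed run-length sequences, plus
hand-traced worked examples and partition/threshold invariants.

## Cohorts

Individuals are allocated to subpopulations by largest-remainder
proportional rounding (deterministic, so mixture composition carries no
sampling variance), and each receives an independent random stream
spawned from the master seed, making results independent of execution
order and bit-reproducible.  Occurrence-rate simulations start at
M0 = d (the healthy resting state) and run 70 years of 365 days (leap
days ignored).  The shipped presets are:

| preset | a | b | c | d | I | role |
|---|---|---|---|---|---|---|
| `single_population` | 4.65 | −3.00 | 0.175 | 5.00 | 0.02 | homogeneous model, OR ≈ 20% |
| `low_risk` | 5.00 | −2.85 | 0.175 | 5.00 | 0.02 | 93% of the mixture, OR ≈ 13% |
| `high_risk` | 4.40 | −3.75 | 0.175 | 4.25 | 0.00 | 7% of the mixture, OR ≈ 100%, chronic course |

Because the one-dimensional dynamics is memoryless, the homogeneous
model's recurrence rates *decrease* with episode number
(RR(1) < OR, RR(2) < RR(1)): a later episode has less remaining lifetime
in which to occur.  Matching the *increasing* empirical recurrence rates
requires the two-subpopulation mixture, which also produces the bimodal
episode-count distribution (P(NDE ≥ 4) exceeding P(2) and P(3)).

`parameter_sweep` runs an independently seeded cohort per grid cell and
reports OR, RR(1), RR(2), median NDE and median first-episode
time-to-remission; per-cell failures are recorded in an `error` column
rather than aborting the sweep.

## Treatment experiments

Treatments are additive parameter shifts applied from day 0 to
individuals who are mid-episode: M0 ~ Uniform(b, 0) (the full symptomatic
range), state machine initialized in the (rebound) depressive-episode
state with onset day 0, horizon 20 years, endpoints censored beyond it.
Arms mix low/high risk 63%/37% — the case composition implied by the
93%/7% weights and subpopulation ORs — and share per-individual streams
and baselines, so the parameter change is the only difference between
arms.  Time-to-response is the first day the mood regains half its
baseline severity (M ≥ M0/2, the standard 50%-reduction response
criterion); time-to-remission is the start of the first qualifying
asymptomatic period plus 14 days (symptoms must be absent 14 days before
remission can be declared).

Named intervention magnitudes (`ad`: Δa = +0.2, Δb = +0.2; `cbt`:
Δc = −0.1; `lifestyle`: ΔI = +2.0) are package conventions chosen to
make the directional effects detectable at n ≈ 500 — the sources print no
post-treatment parameter values — and are freely overridable.  The ΔI
magnitude reflects the year-scale rate units: the escape rate from the
symptomatic well changes by a factor exp(2·ΔI·(c−b)/σ²), so order-one
changes in *I* are needed for an observable effect.  Directional
behavior reproduced by the tests: raising *b* (or *b* and *a* together)
shortens time-to-remission; raising *a* alone or *a* and *d* together
*lengthens* it while lowering the occurrence rate (the antidepressant
paradox); lowering *c* or raising *I* shortens time-to-remission and
lowers occurrence.  Episode-duration distributions are strongly
right-skewed with long tails even though all individuals within a
subpopulation share identical parameters.

## What the simulations do and do not show

The synthetic cohorts emulate lifetime occurrence/recurrence statistics,
onset ages, and episode-duration shapes under the model's assumptions:
one mood dimension, no history dependence, time-homogeneous parameters,
additive white noise, and day-resolution diagnostics.  They do not
emulate measurement noise, diagnostic misclassification, mortality,
comorbidity, age-dependent risk, or treatment nonadherence, so passing
tests validate the implementation and the model's internal consistency,
not clinical forecasting.  Known quantitative limitations at the shipped
calibration: the simulated median age of onset of the two-subpopulation
model is ~22 years, somewhat earlier than the mid-twenties value the
model is meant to reproduce (the high-risk subpopulation's onsets are
fast once its escape rate is set by the shared σ), and the homogeneous
model's RR(2) < RR(1) gap is small, needing cohorts of ~30,000 to
resolve at two standard errors.

## Problem sizes

Scaled-down defaults keep the whole suite fast while leaving sampling
error well inside the stated tolerances: acceptance-style checks use
cohorts of 200–2,000 individuals (binomial SE on OR at n = 1000 is
~1 pp) and treatment arms of 500; the published reference figures use
n = 10,000, available here by raising `n_individuals`.  A 70-year
individual costs ~1 ms, so the full n = 10,000 mixture runs in ~15 s.
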