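# moodcourse

Stochastic mood dynamics and the clinical course of major depressive
disorder (MDD), for computational psychiatry and epidemiological
modeling.

The package combines four pieces:

1. **Bistable mood dynamics.** The state of a person is a single
   continuous variable *M* ("mood"); *M* < 0 means the person is in the
   symptomatic range of MDD.  The mood evolves by Euler–Maruyama steps of
   the stochastic differential equation

   ```
   dM = [ −a (M − b)(M − c)(M − d) + I ] dt + σ dW
   ```

   with *a* > 0 and *b* < *c* < *d*: a double-well system whose stable
   fix points *b* (symptomatic) and *d* (healthy) are separated by the
   unstable fix point *c*.  Gaussian noise drives rare transitions
   between the wells; a constant input *I* tilts the landscape.  Rates
   (*a*, *I*, σ²) are per year; clinical bookkeeping is per day.

2. **A disease-state machine.** Daily symptomatic/asymptomatic signs are
   translated into the clinically defined course: *depressive episode*
   (≥ 14 consecutive symptomatic days), *remission* (≥ 14 asymptomatic
   days), *recovery* (remission spanning ≥ 6 months), *relapse*, and
   *recurrence*, with auxiliary rebound/interrupted states that absorb
   interruptions shorter than 14 days.

3. **Rate algebra and cohort simulation.** Closed forms connect the
   occurrence rate OR = P(NDE ≥ 1) and recurrence rates
   RR(i) = P(NDE ≥ i+1 | NDE ≥ i) with the distribution of the lifetime
   number of depressive episodes (NDE).  Cohorts of seeded individuals —
   either a single population or a 93%/7% mixture of low-risk
   (OR ≈ 13%) and high-risk (OR ≈ 100%) subpopulations — are simulated
   for 70 years and annotated individual by individual.

4. **Treatment experiments.** Antidepressants (Δa, Δb > 0), cognitive
   behavioral therapy (Δc < 0) and life-style change (ΔI > 0) are modeled
   as parameter shifts applied to symptomatic patients, with paired
   treated/control arms sharing noise streams, and time-to-response /
   time-to-remission endpoints with censoring.

## Worked example

Label a 60-day series in which 28 symptomatic days are interrupted by a
5-day asymptomatic gap and followed by 27 more symptomatic days:

```python
import moodcourse as mc

signs = mc.generate_sign_fixture([("neg", 28), ("pos", 5), ("neg", 27)])
ann = mc.annotate_course(mc.runs_from_daily_signs(signs))
print(ann.to_intervals_frame().to_string(index=False))
print(ann.to_episodes_frame().to_string(index=False))
```

```
             label  start_day  end_day  clinically_relevant
DEPRESSIVE_EPISODE          0       28                 True
        REBOUND_DE         28       33                False
DEPRESSIVE_EPISODE         33       60                 True
 onset_day  duration type
         0        60   DE
```

The short gap is a *rebound*, absorbed into a single depressive episode
of 60 days.  Simulating the two-subpopulation cohort reproduces the
familiar epidemiology of MDD:

```python
cfg = mc.CohortConfig(
    subpopulations=(
        mc.SubpopulationSpec("low_risk", 0.93, mc.get_preset("low_risk")),
        mc.SubpopulationSpec("high_risk", 0.07, mc.get_preset("high_risk")),
    ),
    n_individuals=1000, master_seed=42,
)
records = mc.simulate_cohort(cfg)
rates = mc.cohort_rates(records, k_max=3)
print(f"OR = {rates.or_:.3f}")
print("RR =", [round(r, 3) for r in rates.rr])
print(f"median age of onset = {mc.median_age_of_onset(records):.1f} y")
```

```
OR = 0.201
RR = [0.368, 0.676, 0.64]
median age of onset = 24.4 y
```

About 20% of simulated individuals experience at least one depressive
episode over 70 years; of those, ~37% experience a second one, and the
median first onset falls in the mid-twenties.  The NDE distribution is
bimodal: most affected low-risk individuals have exactly one episode,
while the high-risk subpopulation accumulates four or more.

A command-line interface wraps the same functions:

```bash
moodcourse simulate --preset low_risk --n 1000 --seed 1 --out cohort.csv
moodcourse classify --signs daily.csv --out intervals.csv
moodcourse epi --records cohort.csv --out rates.csv
moodcourse treat --intervention cbt --n 500 --seed 1 --out outcomes.csv
moodcourse sweep --param-x a --values-x 4.4,4.65,4.9 \
                 --param-y b --values-y -3.2,-3.0,-2.8 --seed 1 --out sweep.csv
moodcourse calibrate --preset low_risk --target-or 0.13 --seed 1
```

Every command takes an explicit `--seed` and writes byte-identical output
when rerun with the same seed.

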