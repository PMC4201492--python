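"""In-silico treatment experiments: parameter changes in symptomatic patients.

Treatments are modeled as additive changes to a subset of the dynamics
parameters, applied from day 0 of the treatment simulation:

* antidepressants (AD): increase ``a`` and ``b`` (and/or ``d``),
* cognitive behavioral therapy (CBT): decrease ``c``,
* life-style changes: increase ``I``.

Experiments start every individual inside an ongoing depressive episode:
the initial mood is drawn uniformly from the symptomatic range ``(b, 0)``
and the state machine is initialized in the (rebound) depressive-episode
state with episode onset at day 0.  The cohort mixes the low- and
high-risk subpopulations 63%/37% -- the composition of
episode-experiencing individuals implied by 93%/7% mixture weights and
subpopulation occurrence rates of 13% and ~100%.  Treated and control
arms share per-individual random streams and initial moods, so the
parameter change is the only difference between arms.

Endpoints
---------
time-to-response
    First day on which the mood has recovered half of its baseline
    severity (``M >= baseline / 2`` with ``baseline = M0 < 0``), the usual
    "50% reduction in rating-scale score" criterion.
time-to-remission
    Start of the first qualifying (>= 14 d) asymptomatic period, plus 14
    days (symptoms must be absent for 14 days before remission can be
    declared).
Both are censored at the simulation horizon (default 20 years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import allocate_subpopulations
from .disease_states import annotate_course, runs_from_daily_signs
from .dynamics import (
    ConfigurationError,
    DynamicsParameters,
    IntegrationError,
    MoodTrajectory,
    simulate_daily,
)

__all__ = [
    "DEFAULT_TREATMENT_DAYS",
    "CASE_MIX",
    "InterventionSpec",
    "apply_intervention",
    "run_treatment_experiment",
    "time_to_response",
    "time_to_remission",
]

#: Treatment simulation horizon: 20 years.
DEFAULT_TREATMENT_DAYS = 20 * 365

#: Share of episode-experiencing individuals in the low-/high-risk
#: subpopulations (from 93%/7% weights and ORs of 13%/~100%).
CASE_MIX = (0.63, 0.37)

_DELTA_KEYS = ("a", "b", "c", "d", "I")


@dataclass(frozen=True)
class InterventionSpec:
    """Additive parameter changes applied at treatment onset."""

    name: str
    deltas: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.deltas) - set(_DELTA_KEYS)
        if unknown:
            raise ConfigurationError(
                f"intervention may only change {_DELTA_KEYS}, got {sorted(unknown)}"
            )
        object.__setattr__(self, "deltas", dict(self.deltas))


def apply_intervention(
    params: DynamicsParameters, spec: InterventionSpec
) -> DynamicsParameters:
    """Element-wise addition of the intervention deltas, with validation.

    Raises :class:`ConfigurationError` if the post-treatment parameters
    violate the model invariants (``a > 0``, ``b < c < d``).
    """
    changes = {
        key: getattr(params, key) + delta for key, delta in spec.deltas.items()
    }
    return params.replace(**changes)


def time_to_response(traj: MoodTrajectory, baseline: float):
    """First day with ``M >= baseline / 2``, or ``None`` if censored.

    ``baseline`` is the (negative) pre-treatment mood; severity is its
    magnitude, so crossing ``baseline / 2`` halves the severity.  Day 0 is
    the initial value; later days are end-of-day samples.
    """
    if not baseline < 0:
        raise ValueError(f"baseline must be negative, got {baseline}")
    threshold = 0.5 * baseline
    if traj.values[0] >= threshold:
        return 0
    hits = np.flatnonzero(traj.daily_values() >= threshold)
    return int(hits[0]) + 1 if hits.size else None


def _response_day_from_daily(M0: float, daily: np.ndarray, baseline: float):
    if M0 >= 0.5 * baseline:
        return 0
    hits = np.flatnonzero(daily >= 0.5 * baseline)
    return int(hits[0]) + 1 if hits.size else None


def time_to_remission(annotation) -> Optional[int]:
    """Onset of the first remission/recovery period plus 14 d, or ``None``."""
    day = annotation.first_remission_day()
    return None if day is None else int(day) + 14


def run_treatment_experiment(
    control: Mapping[str, DynamicsParameters],
    spec: InterventionSpec,
    n: int = 500,
    duration_days: int = DEFAULT_TREATMENT_DAYS,
    seed: int = 0,
    case_mix: Sequence[float] = CASE_MIX,
) -> pd.DataFrame:
    """Paired treated/control experiment on symptomatic individuals.

    ``control`` maps subpopulation names (conventionally ``low_risk`` and
    ``high_risk``) to their untreated parameter sets; ``case_mix`` gives
    the corresponding arm composition.  Returns one row per individual and
    arm with the endpoints and censoring flags.
    """
    names = list(control)
    if len(names) != len(tuple(case_mix)):
        raise ConfigurationError("case_mix must have one weight per subpopulation")
    if abs(sum(case_mix) - 1.0) > 1e-9:
        raise ConfigurationError(f"case_mix must sum to 1, got {sum(case_mix)}")
    arms = {
        "control": {name: control[name] for name in names},
        "treated": {name: apply_intervention(control[name], spec) for name in names},
    }
    assignment = allocate_subpopulations(list(case_mix), n)
    streams = np.random.SeedSequence(seed).spawn(n)
    rows = []
    for i, (sub_idx, stream) in enumerate(zip(assignment, streams)):
        name = names[sub_idx]
        init_seq, noise_seq = stream.spawn(2)
        # baseline mood: uniform on the symptomatic range of the *control*
        # parameters, shared by both arms
        init_rng = np.random.Generator(np.random.PCG64(init_seq))
        M0 = float(init_rng.uniform(control[name].b, 0.0))
        for arm, params_by_name in arms.items():
            params = params_by_name[name]
            noise_rng = np.random.Generator(np.random.PCG64(noise_seq))
            try:
                daily = simulate_daily(params, duration_days, M0, noise_rng)
            except IntegrationError as err:
                raise IntegrationError(
                    f"individual {i} ({name}, {arm} arm): {err}"
                ) from err
            ann = annotate_course(
                runs_from_daily_signs(daily < 0.0), initial_state="ongoing_episode"
            )
            ttr = time_to_remission(ann)
            resp = _response_day_from_daily(M0, daily, M0)
            first_episode = ann.episodes[0]
            episode_censored = ttr is None
            rows.append(
                {
                    "individual": i,
                    "arm": arm,
                    "subpopulation": name,
                    "baseline_mood": M0,
                    "time_to_response": math.nan if resp is None else float(resp),
                    "response_censored": resp is None,
                    "time_to_remission": math.nan if ttr is None else float(ttr),
                    "remission_censored": episode_censored,
                    "episode_duration": float(first_episode.duration),
                    "episode_censored": episode_censored,
                    "nde": len(ann.episodes),
                }
            )
    return pd.DataFrame(rows)


def survival_table(times: Sequence[float], censored: Sequence[bool]) -> pd.DataFrame:
    """Kaplan-Meier-style event table (time, n_at_risk, events) for export."""
    frame = pd.DataFrame({"time": times, "censored": censored})
    frame["time"] = frame["time"].fillna(np.inf)
    event_times = np.sort(frame.loc[~frame["censored"], "time"].unique())
    rows = []
    for t in event_times:
        rows.append(
            {
                "time": t,
                "n_at_risk": int((frame["time"] >= t).sum()),
                "events": int(((frame["time"] == t) & ~frame["censored"]).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "events"])
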