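"""Finite-state machine turning daily symptom signs into disease states.

The clinical course of major depressive disorder is described with four
clinically relevant states -- depressive episode (DE), remission, recovery
and relapse -- plus auxiliary states that absorb short, clinically
irrelevant interruptions.  The machine consumes a sequence of daily
symptomatic/asymptomatic flags, run-length encoded into alternating runs,
and emits a labeled partition of the timeline together with the derived
episode list.

Rules
-----
* A depressive episode requires at least ``episode_threshold`` (default 14)
  consecutive symptomatic days.
* Interruptions shorter than 14 days never change the clinically relevant
  state: an asymptomatic gap inside an episode is a *rebound* and is added
  to the episode's duration; a symptomatic blip inside remission/recovery
  is an *interrupted remission*/*interrupted recovery* and is added to that
  period's duration.
* An asymptomatic run of >= 14 days ends the episode and starts remission.
* A symptomatic run of >= 14 days during remission is a relapse (a new
  episode); during recovery it is a recurrence (a new depressive episode).
* When the total span of a remission period -- asymptomatic runs plus
  absorbed short symptomatic interruptions -- reaches ``recovery_span``
  (default 180 days, i.e. six months), the whole period is retroactively
  relabeled recovery from its onset.

An unterminated final run keeps its in-progress label; in particular a
trailing symptomatic run of >= 14 days counts as an episode.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EPISODE_THRESHOLD",
    "DEFAULT_RECOVERY_SPAN",
    "DiseaseState",
    "SignRun",
    "Interval",
    "Episode",
    "CourseAnnotation",
    "runs_from_daily_signs",
    "annotate_course",
    "count_episodes",
    "episode_durations",
]

#: Minimum consecutive symptomatic days to qualify as a depressive episode,
#: and maximum length of an absorbed interruption (days).
DEFAULT_EPISODE_THRESHOLD = 14

#: Remission span (days) after which a remission becomes a recovery.
DEFAULT_RECOVERY_SPAN = 180


class DiseaseState(enum.Enum):
    """The nine disease states; four are clinically relevant."""

    NULL = "NULL"
    DEPRESSIVE_EPISODE = "DEPRESSIVE_EPISODE"
    REBOUND_DE = "REBOUND_DE"
    REMISSION = "REMISSION"
    INTERRUPTED_REMISSION = "INTERRUPTED_REMISSION"
    RECOVERY = "RECOVERY"
    INTERRUPTED_RECOVERY = "INTERRUPTED_RECOVERY"
    RELAPSE = "RELAPSE"
    REBOUND_RELAPSE = "REBOUND_RELAPSE"

    @property
    def clinically_relevant(self) -> bool:
        return self in _CLINICAL


_CLINICAL = {
    DiseaseState.DEPRESSIVE_EPISODE,
    DiseaseState.REMISSION,
    DiseaseState.RECOVERY,
    DiseaseState.RELAPSE,
}


@dataclass(frozen=True)
class SignRun:
    """A maximal run of equal daily signs."""

    symptomatic: bool
    start_day: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"run length must be >= 1, got {self.length}")


@dataclass
class Interval:
    """A labeled half-open interval ``[start_day, end_day)`` of the timeline."""

    label: DiseaseState
    start_day: int
    end_day: int

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


@dataclass(frozen=True)
class Episode:
    """One depressive episode (including absorbed rebound interruptions)."""

    onset_day: int
    duration: int
    kind: Literal["DE", "RELAPSE"]


@dataclass
class CourseAnnotation:
    """Disease-state partition of a simulated (or observed) timeline."""

    intervals: List[Interval]
    episodes: List[Episode]
    total_days: int
    runs: List[SignRun] = field(default_factory=list)

    def to_intervals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [iv.label.value for iv in self.intervals],
                "start_day": [iv.start_day for iv in self.intervals],
                "end_day": [iv.end_day for iv in self.intervals],
                "clinically_relevant": [
                    iv.label.clinically_relevant for iv in self.intervals
                ],
            }
        )

    def to_episodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_day": [e.onset_day for e in self.episodes],
                "duration": [e.duration for e in self.episodes],
                "type": [e.kind for e in self.episodes],
            }
        )

    def first_remission_day(self):
        """Start of the first remission (or recovery) period, or ``None``."""
        for iv in self.intervals:
            if iv.label in (DiseaseState.REMISSION, DiseaseState.RECOVERY):
                return iv.start_day
        return None


def runs_from_daily_signs(signs: Sequence[bool]) -> List[SignRun]:
    """Run-length encode a daily symptomatic/asymptomatic sequence."""
    arr = np.asarray(signs, dtype=bool)
    if arr.size == 0:
        raise ValueError("empty sign sequence")
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return [
        SignRun(symptomatic=bool(arr[s]), start_day=int(s), length=int(e - s))
        for s, e in zip(starts, ends)
    ]


def annotate_course(
    runs: Sequence[SignRun],
    *,
    episode_threshold: int = DEFAULT_EPISODE_THRESHOLD,
    recovery_span: int = DEFAULT_RECOVERY_SPAN,
    initial_state: Literal["null", "ongoing_episode"] = "null",
) -> CourseAnnotation:
    """Label a run sequence with disease states and extract episodes.

    With ``initial_state='ongoing_episode'`` the machine starts inside a
    depressive episode with onset at day 0 (used for treatment experiments
    where individuals enter the simulation mid-episode).
    """
    runs = list(runs)
    if not runs:
        raise ValueError("empty run list")
    for prev, nxt in zip(runs, runs[1:]):
        if prev.symptomatic == nxt.symptomatic:
            raise ValueError("consecutive runs must alternate sign")
        if nxt.start_day != prev.start_day + prev.length:
            raise ValueError("runs must tile the timeline without gaps")
    if runs[0].start_day != 0:
        raise ValueError("first run must start at day 0")

    thresh = int(episode_threshold)
    span = int(recovery_span)
    intervals: List[Interval] = []
    episodes: List[dict] = []

    # context: 'null' | 'episode' | 'rest'  ('rest' = remission or recovery)
    if initial_state == "ongoing_episode":
        context = "episode"
        episodes.append({"onset": 0, "end": None, "kind": "DE"})
    elif initial_state == "null":
        context = "null"
    else:
        raise ValueError(f"unknown initial_state {initial_state!r}")
    episode_kind = "DE"          # kind of the episode currently in progress
    recovered = False            # has the current rest period become recovery
    rest_span = 0                # cumulative days of the current rest period
    rest_intervals: List[Interval] = []  # intervals of the current rest period

    def promote_if_due() -> None:
        nonlocal recovered
        if not recovered and rest_span >= span:
            recovered = True
            for iv in rest_intervals:
                if iv.label is DiseaseState.REMISSION:
                    iv.label = DiseaseState.RECOVERY
                elif iv.label is DiseaseState.INTERRUPTED_REMISSION:
                    iv.label = DiseaseState.INTERRUPTED_RECOVERY

    for run in runs:
        start, end = run.start_day, run.start_day + run.length
        if context == "null":
            # Short symptomatic blips and any asymptomatic stretch stay NULL.
            if run.symptomatic and run.length >= thresh:
                context, episode_kind = "episode", "DE"
                episodes.append({"onset": start, "end": None, "kind": "DE"})
                intervals.append(Interval(DiseaseState.DEPRESSIVE_EPISODE, start, end))
            else:
                intervals.append(Interval(DiseaseState.NULL, start, end))

        elif context == "episode":
            de_label = (
                DiseaseState.DEPRESSIVE_EPISODE
                if episode_kind == "DE"
                else DiseaseState.RELAPSE
            )
            if run.symptomatic:
                # Any symptomatic run continues the ongoing episode.
                intervals.append(Interval(de_label, start, end))
            elif run.length < thresh:
                rebound = (
                    DiseaseState.REBOUND_DE
                    if episode_kind == "DE"
                    else DiseaseState.REBOUND_RELAPSE
                )
                intervals.append(Interval(rebound, start, end))
            else:
                # Qualifying asymptomatic run: episode ends, remission begins.
                episodes[-1]["end"] = start
                context = "rest"
                recovered = False
                rest_span = run.length
                iv = Interval(DiseaseState.REMISSION, start, end)
                intervals.append(iv)
                rest_intervals = [iv]
                promote_if_due()

        else:  # context == "rest"
            if not run.symptomatic:
                label = DiseaseState.RECOVERY if recovered else DiseaseState.REMISSION
                iv = Interval(label, start, end)
                intervals.append(iv)
                rest_intervals.append(iv)
                rest_span += run.length
                promote_if_due()
            elif run.length < thresh:
                label = (
                    DiseaseState.INTERRUPTED_RECOVERY
                    if recovered
                    else DiseaseState.INTERRUPTED_REMISSION
                )
                iv = Interval(label, start, end)
                intervals.append(iv)
                rest_intervals.append(iv)
                rest_span += run.length  # absorbed interruptions count
                promote_if_due()
            else:
                # Qualifying symptomatic run: relapse before recovery,
                # recurrence (new DE) after recovery.
                kind = "DE" if recovered else "RELAPSE"
                context, episode_kind = "episode", kind
                episodes.append({"onset": start, "end": None, "kind": kind})
                label = (
                    DiseaseState.DEPRESSIVE_EPISODE
                    if kind == "DE"
                    else DiseaseState.RELAPSE
                )
                intervals.append(Interval(label, start, end))

    total_days = runs[-1].start_day + runs[-1].length
    episode_list = [
        Episode(
            onset_day=e["onset"],
            duration=(e["end"] if e["end"] is not None else total_days) - e["onset"],
            kind=e["kind"],
        )
        for e in episodes
    ]
    return CourseAnnotation(
        intervals=intervals,
        episodes=episode_list,
        total_days=total_days,
        runs=runs,
    )


def count_episodes(
    annotation: CourseAnnotation,
    mode: Literal["all_episodes", "post_recovery_only"] = "all_episodes",
) -> int:
    """Number of depressive episodes (NDE) over the annotated timeline.

    ``all_episodes`` (default) counts every depressive-episode and relapse
    onset.  ``post_recovery_only`` counts only episodes entered from the
    null or recovery state, matching the stricter reading in which a new
    episode requires a preceding recovery.
    """
    if mode == "all_episodes":
        return len(annotation.episodes)
    if mode == "post_recovery_only":
        return sum(1 for e in annotation.episodes if e.kind == "DE")
    raise ValueError(f"unknown mode {mode!r}")


def episode_durations(annotation: CourseAnnotation) -> List[int]:
    """Per-episode durations in days, rebound interruptions included."""
    return [e.duration for e in annotation.episodes]
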