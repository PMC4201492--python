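"""Cohort simulation: populations of individuals, lifetime disease courses.

A cohort is a mixture of subpopulations, each sharing one set of dynamics
parameters.  Every individual gets an independent, deterministically
derived random stream (spawned from the master seed), is integrated for
the full simulated lifetime (default 70 years), and has its daily sign
sequence annotated by the disease-state machine.  Cohort-level statistics
(occurrence rate, recurrence rates, median age of onset, episode-duration
summaries) are computed from the per-individual records.

Individuals are assigned to subpopulations by deterministic proportional
allocation (largest-remainder rounding), not randomly, so the mixture
composition carries no sampling variance.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .disease_states import annotate_course, count_episodes, runs_from_daily_signs
from .dynamics import (
    ConfigurationError,
    DynamicsParameters,
    IntegrationError,
    simulate_daily,
)
from .epidemiology import RateSet, recurrence_rates

__all__ = [
    "DEFAULT_LIFETIME_DAYS",
    "SubpopulationSpec",
    "CohortConfig",
    "simulate_cohort",
    "cohort_rates",
    "median_age_of_onset",
    "calibrate_noise",
    "parameter_sweep",
]

logger = logging.getLogger("moodcourse")

#: Simulated lifetime: 70 years of 365 days (leap days ignored).
DEFAULT_LIFETIME_DAYS = 70 * 365


@dataclass(frozen=True)
class SubpopulationSpec:
    """One mixture component of a cohort."""

    name: str
    weight: float
    params: DynamicsParameters
    init_policy: Literal["at_positive_fixpoint", "uniform_negative"] = (
        "at_positive_fixpoint"
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigurationError(
                f"subpopulation weight must be in [0, 1], got {self.weight}"
            )
        if self.init_policy not in ("at_positive_fixpoint", "uniform_negative"):
            raise ConfigurationError(f"unknown init policy {self.init_policy!r}")


@dataclass(frozen=True)
class CohortConfig:
    """A full cohort simulation request."""

    subpopulations: tuple
    n_individuals: int
    master_seed: int
    duration_days: int = DEFAULT_LIFETIME_DAYS
    count_mode: str = "all_episodes"

    def __post_init__(self) -> None:
        subs = tuple(self.subpopulations)
        if not subs:
            raise ConfigurationError("at least one subpopulation is required")
        total = sum(s.weight for s in subs)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"subpopulation weights must sum to 1, got {total}"
            )
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.duration_days < 1:
            raise ConfigurationError("duration_days must be >= 1")
        if self.master_seed is None:
            raise ConfigurationError("a master seed is required")
        object.__setattr__(self, "subpopulations", subs)


def allocate_subpopulations(weights: Sequence[float], n: int) -> np.ndarray:
    """Deterministic proportional allocation (largest remainder).

    Returns the subpopulation index of each of the ``n`` individuals;
    individuals of the same subpopulation are contiguous.
    """
    w = np.asarray(weights, dtype=float)
    ideal = w * n
    base = np.floor(ideal).astype(int)
    rem = n - base.sum()
    if rem:
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:rem]] += 1
    return np.repeat(np.arange(w.size), base)


def _initial_mood(spec: SubpopulationSpec, rng: np.random.Generator) -> float:
    if spec.init_policy == "at_positive_fixpoint":
        return spec.params.d
    # uniform on the symptomatic range (b, 0)
    return float(rng.uniform(spec.params.b, 0.0))


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate and annotate every individual of a cohort.

    Returns a tidy frame with one row per individual:

    ``individual, subpopulation, nde, nde_post_recovery, first_onset_day,
    first_remission_day, episode_durations`` (onset/remission days are NaN
    for unaffected individuals; ``episode_durations`` is a list).
    """
    assignment = allocate_subpopulations(
        [s.weight for s in config.subpopulations], config.n_individuals
    )
    master = config.master_seed
    if not isinstance(master, np.random.SeedSequence):
        master = np.random.SeedSequence(master)
    streams = master.spawn(config.n_individuals)
    rows = []
    t0 = time.monotonic()
    for i, (sub_idx, stream) in enumerate(zip(assignment, streams)):
        spec = config.subpopulations[sub_idx]
        # independent substreams: one for initialization, one for the noise
        init_seq, noise_seq = stream.spawn(2)
        init_rng = np.random.Generator(np.random.PCG64(init_seq))
        noise_rng = np.random.Generator(np.random.PCG64(noise_seq))
        M0 = _initial_mood(spec, init_rng)
        try:
            daily = simulate_daily(spec.params, config.duration_days, M0, noise_rng)
        except IntegrationError as err:
            raise IntegrationError(f"individual {i} ({spec.name}): {err}") from err
        ann = annotate_course(runs_from_daily_signs(daily < 0.0))
        episodes = ann.episodes
        rows.append(
            {
                "individual": i,
                "subpopulation": spec.name,
                "nde": count_episodes(ann, "all_episodes"),
                "nde_post_recovery": count_episodes(ann, "post_recovery_only"),
                "first_onset_day": float(episodes[0].onset_day)
                if episodes
                else math.nan,
                "first_remission_day": float(ann.first_remission_day())
                if ann.first_remission_day() is not None
                else math.nan,
                "episode_durations": [e.duration for e in episodes],
            }
        )
        if (i + 1) % 1000 == 0:
            logger.info(
                "simulated %d/%d individuals (%.1f s elapsed)",
                i + 1,
                config.n_individuals,
                time.monotonic() - t0,
            )
    logger.info(
        "cohort of %d individuals done in %.1f s",
        config.n_individuals,
        time.monotonic() - t0,
    )
    return pd.DataFrame(rows)


def cohort_rates(
    records: pd.DataFrame, k_max: int = 3, count_mode: str = "all_episodes"
) -> RateSet:
    """Empirical occurrence and recurrence rates of a simulated cohort."""
    col = "nde" if count_mode == "all_episodes" else "nde_post_recovery"
    return recurrence_rates(records[col].to_numpy(), k_max)


def median_age_of_onset(records: pd.DataFrame) -> float:
    """Median age (years) at first episode onset among affected individuals."""
    onsets = records["first_onset_day"].dropna()
    if onsets.empty:
        raise ValueError("no affected individuals in the cohort")
    return float(np.median(onsets) / 365.0)


def _single_param_cohort(
    params: DynamicsParameters,
    n: int,
    duration_days: int,
    seed: int,
) -> pd.DataFrame:
    cfg = CohortConfig(
        subpopulations=(SubpopulationSpec("cohort", 1.0, params),),
        n_individuals=n,
        master_seed=seed,
        duration_days=duration_days,
    )
    return simulate_cohort(cfg)


def calibrate_noise(
    params: DynamicsParameters,
    target_or: float,
    duration_days: int = DEFAULT_LIFETIME_DAYS,
    n: int = 500,
    seed: int = 0,
    bracket: tuple = (4.0, 16.0),
    tol: float = 0.01,
    max_iter: int = 30,
) -> float:
    """Find sigma such that the simulated occurrence rate hits ``target_or``.

    Monotone bisection on sigma of the simulated lifetime occurrence rate
    (escape from the healthy well becomes more likely with more noise over
    the searched bracket).  All evaluations reuse the same master seed
    (common random numbers), which makes the empirical OR(sigma) curve
    effectively monotone and the bisection stable.  Returns sigma with the
    simulated OR within ``tol`` of the target at the given ``n``.
    """
    if not 0.0 < target_or < 1.0:
        raise ConfigurationError(
            f"target occurrence rate must be in (0, 1), got {target_or}"
        )

    def simulated_or(sigma: float) -> float:
        records = _single_param_cohort(
            params.replace(sigma=sigma), n, duration_days, seed
        )
        return float((records["nde"] >= 1).mean())

    lo, hi = bracket
    or_lo, or_hi = simulated_or(lo), simulated_or(hi)
    if not or_lo <= target_or <= or_hi:
        raise ConfigurationError(
            f"target OR {target_or} not bracketed: OR({lo}) = {or_lo}, "
            f"OR({hi}) = {or_hi}"
        )
    sigma = 0.5 * (lo + hi)
    for _ in range(max_iter):
        sigma = 0.5 * (lo + hi)
        value = simulated_or(sigma)
        logger.info("calibrate_noise: sigma=%.4f -> OR=%.4f", sigma, value)
        if abs(value - target_or) <= tol:
            return sigma
        if value < target_or:
            lo = sigma
        else:
            hi = sigma
        if hi - lo < 1e-3:
            return 0.5 * (lo + hi)
    return sigma


def parameter_sweep(
    base_params: DynamicsParameters,
    param_x: str,
    values_x: Sequence[float],
    param_y: str,
    values_y: Sequence[float],
    n: int = 200,
    duration_days: int = DEFAULT_LIFETIME_DAYS,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Grid sweep over two dynamics parameters of a single-population model.

    Each grid cell simulates an independent, individually seeded cohort and
    reports occurrence rate, first/second recurrence rates, median episode
    count, and the median first-episode time-to-remission (days from onset
    to the start of the qualifying asymptomatic run, plus the 14 diagnostic
    days).  Per-cell failures are recorded in the ``error`` column rather
    than aborting the sweep.
    """
    for name in (param_x, param_y):
        if name not in ("a", "b", "c", "d", "I", "sigma"):
            raise ConfigurationError(f"cannot sweep parameter {name!r}")
    cells = [(x, y) for x in values_x for y in values_y]
    seeds = np.random.SeedSequence(master_seed).spawn(len(cells))
    rows = []
    for (x, y), cell_seed in zip(cells, seeds):
        row = {param_x: x, param_y: y, "error": ""}
        try:
            params = base_params.replace(**{param_x: x, param_y: y})
            records = _single_param_cohort(params, n, duration_days, cell_seed)
            rates = cohort_rates(records, k_max=2)
            affected = records[records["nde"] >= 1]
            ttr = affected["first_remission_day"] - affected["first_onset_day"] + 14
            row.update(
                {
                    "or": rates.or_,
                    "rr1": rates.rr[0],
                    "rr2": rates.rr[1],
                    "median_nde": float(records["nde"].median()),
                    "median_ttr_days": float(ttr.dropna().median())
                    if ttr.notna().any()
                    else math.nan,
                }
            )
        except (ConfigurationError, IntegrationError) as err:
            row.update(
                {
                    "or": math.nan,
                    "rr1": math.nan,
                    "rr2": math.nan,
                    "median_nde": math.nan,
                    "median_ttr_days": math.nan,
                    "error": str(err),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
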