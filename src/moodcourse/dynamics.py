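"""Bistable stochastic dynamics of a one-dimensional mood variable.

The state of a person is a single continuous variable ``M`` ("mood").
``M < 0`` means the person is in the symptomatic range of major depressive
disorder, ``M >= 0`` means asymptomatic.  The deterministic part of the
dynamics is a cubic polynomial with three roots ``b < c < d``: two stable
fix points (``b``, the symptomatic resting state, and ``d``, the healthy
resting state) separated by an unstable fix point ``c`` that acts as the
separatrix between the two basins of attraction.  A constant external
input ``I`` tilts the double well and additive Gaussian noise drives
stochastic transitions between the wells.

Units
-----
Mood is dimensionless.  The *dynamics* evolves on a timescale of years:
``a`` and ``I`` are rates per year, ``sigma`` is mood units per
square-root year, and the integration step ``dt`` is expressed in years.
Clinical bookkeeping (episode thresholds, trajectory day indices) is in
days; the two are linked by sampling the trajectory once per calendar
day.  This split matches the phenomenology the model targets: lifetime
occurrence risks accumulate over decades while the diagnostic criteria
count days.

Integration is explicit Euler-Maruyama::

    M(t + dt) = M(t) + dt * drift(M(t)) + sigma * sqrt(dt) * z,   z ~ N(0, 1)

with one independent standard-normal draw per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "DEFAULT_DT",
    "DEFAULT_SIGMA",
    "ConfigurationError",
    "IntegrationError",
    "DynamicsParameters",
    "MoodTrajectory",
    "drift",
    "simulate_trajectory",
    "simulate_daily",
    "daily_signs",
]

DAYS_PER_YEAR = 365

#: Default integration step in years: four Euler steps per calendar day.
DEFAULT_DT = 1.0 / (4 * DAYS_PER_YEAR)

#: Default noise amplitude (mood units per square-root year).  Fixed once by
#: bisection on the low-risk parameter set so that the simulated lifetime
#: occurrence rate of a 70-year cohort equals 13% (see cohort.calibrate_noise
#: and docs/methods.md); shipped as a frozen constant so that all presets and
#: examples are reproducible without re-running the calibration.
DEFAULT_SIGMA = 10.55

#: Trajectories whose |M| exceeds ``DIVERGENCE_FACTOR * max(|b|, |d|)`` abort
#: with an IntegrationError; finite-noise sample paths of the cubic well stay
#: orders of magnitude below this.
DIVERGENCE_FACTOR = 100.0


class ConfigurationError(ValueError):
    """Invalid model or run configuration."""


class IntegrationError(RuntimeError):
    """Numerical failure (divergence) during trajectory integration."""


@dataclass(frozen=True)
class DynamicsParameters:
    """Constants of one simulated individual.

    Parameters
    ----------
    a:
        Drift-rate coefficient (per year per squared mood unit), ``a > 0``.
        Sets how fast the mood relaxes to the nearest stable fix point.
    b, c, d:
        Roots of the cubic drift, ``b < c < d`` (mood units).  ``b`` and
        ``d`` are the stable symptomatic/healthy resting states, ``c`` the
        unstable separatrix.
    I:
        Constant external input (mood units per year).
    sigma:
        Noise amplitude (mood units per square-root year), ``sigma >= 0``.
    dt:
        Euler integration step in years.  Must resolve the fastest local
        relaxation rate: ``dt < 2 / (a * (d - b) * (d - c))``, the explicit
        Euler stability bound at the healthy fix point.
    """

    a: float
    b: float
    c: float
    d: float
    I: float = 0.0
    sigma: float = DEFAULT_SIGMA
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d, self.I, self.sigma, self.dt)
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError(f"non-finite parameter in {vals}")
        if self.a <= 0:
            raise ConfigurationError(f"a must be positive, got a={self.a}")
        if not (self.b < self.c < self.d):
            raise ConfigurationError(
                f"fix points must be ordered b < c < d, got "
                f"b={self.b}, c={self.c}, d={self.d}"
            )
        if self.sigma < 0:
            raise ConfigurationError(f"sigma must be >= 0, got {self.sigma}")
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.dt >= self.stability_limit:
            raise ConfigurationError(
                f"dt={self.dt} violates the explicit-Euler stability bound "
                f"2/(a*(d-b)*(d-c)) = {self.stability_limit:.6g}"
            )

    @property
    def stability_limit(self) -> float:
        """Largest admissible ``dt``: ``2 / (a * (d - b) * (d - c))``."""
        return 2.0 / (self.a * (self.d - self.b) * (self.d - self.c))

    @property
    def steps_per_day(self) -> int:
        """Number of Euler steps per calendar day implied by ``dt``."""
        spd = 1.0 / (DAYS_PER_YEAR * self.dt)
        n = max(1, round(spd))
        if abs(spd - n) > 1e-9 * n:
            raise ConfigurationError(
                f"dt={self.dt} does not give an integer number of steps per "
                f"day (got {spd}); use dt = 1/(365*k) for integer k"
            )
        return n

    @property
    def divergence_bound(self) -> float:
        return DIVERGENCE_FACTOR * max(abs(self.b), abs(self.d))

    def replace(self, **changes) -> "DynamicsParameters":
        """Return a validated copy with the given fields replaced."""
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class MoodTrajectory:
    """A simulated mood time course.

    ``values[i]`` is the mood at time ``i * dt`` years after the start;
    ``values[0]`` is the initial condition.  ``start_day`` anchors the
    trajectory on the calendar-day axis used by the disease-state machine.
    """

    dt: float
    values: np.ndarray
    seed: object = None
    start_day: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ConfigurationError("trajectory values must be a non-empty 1-d array")
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("trajectory contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n_steps(self) -> int:
        return self.values.size - 1

    @property
    def n_days(self) -> int:
        """Number of complete calendar days covered."""
        return int(math.floor(self.n_steps * self.dt * DAYS_PER_YEAR + 1e-9))

    def to_frame(self, stride: int = 1):
        """Tidy day/mood/sign table, optionally down-sampled every ``stride`` days."""
        import pandas as pd

        if stride < 1:
            raise ConfigurationError(f"stride must be >= 1, got {stride}")
        daily = self.daily_values()
        days = np.arange(self.start_day, self.start_day + daily.size)
        frame = pd.DataFrame(
            {
                "day": days,
                "mood": daily,
                "sign": np.where(daily < 0.0, "neg", "pos"),
            }
        )
        return frame.iloc[::stride].reset_index(drop=True)

    def daily_values(self) -> np.ndarray:
        """Mood sampled at the end of each complete calendar day."""
        n_days = self.n_days
        if n_days < 1:
            raise ConfigurationError("trajectory does not cover a full day")
        idx = np.round((np.arange(1, n_days + 1)) / (DAYS_PER_YEAR * self.dt))
        idx = np.minimum(idx.astype(np.int64), self.n_steps)
        return self.values[idx]


def drift(M, params: DynamicsParameters):
    """Deterministic mood change rate ``-a (M-b)(M-c)(M-d) + I``.

    Accepts scalars or arrays; the rate is in mood units per year.  With
    ``I = 0`` the rate vanishes exactly at the three fix points.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("mood value must be finite")
    out = (
        -params.a * (M - params.b) * (M - params.c) * (M - params.d) + params.I
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Euler-Maruyama kernel.  The hot loop is compiled with numba when available;
# the pure-python fallback is functionally identical (same RNG draw order).
# ---------------------------------------------------------------------------

def _kernel_py(rng, M0, a, b, c, d, I, sigma, sqdt, dt, n_steps, stride, out, bound):
    M = M0
    r = 0
    for s in range(1, n_steps + 1):
        f = -a * (M - b) * (M - c) * (M - d) + I
        M = M + dt * f + sigma * sqdt * rng.standard_normal()
        if not (abs(M) <= bound):
            return s
        if s % stride == 0 and r < out.size:
            out[r] = M
            r += 1
    return 0


try:  # pragma: no cover - exercised through the public API
    from numba import njit as _njit

    _kernel = _njit(cache=True)(_kernel_py)
except ImportError:  # pragma: no cover
    _kernel = _kernel_py


def _integrate(params: DynamicsParameters, n_steps: int, M0: float, rng, stride: int,
               n_record: int) -> np.ndarray:
    """Run the Euler-Maruyama recursion, recording every ``stride``-th value."""
    out = np.empty(n_record, dtype=float)
    status = _kernel(
        rng, float(M0), params.a, params.b, params.c, params.d, params.I,
        params.sigma, math.sqrt(params.dt), params.dt, int(n_steps),
        int(stride), out, params.divergence_bound,
    )
    if status:
        raise IntegrationError(
            f"trajectory diverged (|M| > {params.divergence_bound:g}) at "
            f"step {status} (t = {status * params.dt:.4g} y); "
            f"reduce dt or sigma"
        )
    return out


def simulate_trajectory(params: DynamicsParameters, duration_days: float,
                        M0: float, seed) -> MoodTrajectory:
    """Simulate ``M`` for ``duration_days`` starting from ``M0``.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; identical
    inputs give bit-identical trajectories across runs and platforms.
    """
    if duration_days <= 0:
        raise ConfigurationError(f"duration must be positive, got {duration_days}")
    if not math.isfinite(M0):
        raise ConfigurationError(f"initial mood must be finite, got {M0}")
    n_steps = int(round(duration_days / (DAYS_PER_YEAR * params.dt)))
    if n_steps < 1:
        raise ConfigurationError("duration shorter than one integration step")
    rng = np.random.Generator(np.random.PCG64(seed))
    values = np.empty(n_steps + 1, dtype=float)
    values[0] = M0
    values[1:] = _integrate(params, n_steps, M0, rng, 1, n_steps)
    return MoodTrajectory(dt=params.dt, values=values, seed=seed)


def simulate_daily(params: DynamicsParameters, n_days: int, M0: float,
                   rng) -> np.ndarray:
    """End-of-day mood samples for ``n_days`` days (cohort fast path).

    Functionally equivalent to
    ``simulate_trajectory(...).daily_values()`` but records only one value
    per day, which keeps 70-year cohorts cheap.  ``rng`` is a
    ``numpy.random.Generator`` so callers control per-individual streams.
    """
    spd = params.steps_per_day
    return _integrate(params, n_days * spd, M0, rng, spd, n_days)


def daily_signs(traj: MoodTrajectory) -> np.ndarray:
    """Boolean symptomatic flag per calendar day.

    Day ``k`` is symptomatic iff the mood sampled at the end of day ``k``
    is strictly negative; an exact zero counts as asymptomatic.
    """
    return traj.daily_values() < 0.0


def signs_from_values(daily: Sequence[float]) -> np.ndarray:
    """Symptomatic flags from an externally supplied daily mood series."""
    daily = np.asarray(daily, dtype=float)
    if daily.size == 0:
        raise ConfigurationError("empty daily mood series")
    if not np.all(np.isfinite(daily)):
        raise ConfigurationError("daily mood series contains non-finite values")
    return daily < 0.0
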