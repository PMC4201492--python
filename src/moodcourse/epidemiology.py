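"""Occurrence/recurrence-rate algebra and the episode-count distribution.

The lifetime occurrence rate ``OR`` is the fraction of a population with at
least one depressive episode.  The *i*-th recurrence rate ``RR(i)`` is the
conditional probability of at least ``i + 1`` episodes given at least
``i``.  Both are in closed-form correspondence with the distribution of
the number of depressive episodes (NDE)::

    P(NDE = 0) = 1 - OR
    P(NDE = j) = OR * RR(1) * ... * RR(j-1) * (1 - RR(j))        (j >= 1)
    P(NDE >= k) = OR * RR(1) * ... * RR(k-1)

Distributions carry an explicit tail bucket ``P(NDE >= k)`` (default
``k = 4``), the granularity at which epidemiological studies usually
report episode counts.

Empirical rates with an empty denominator are reported as NaN
("undefined"), never as zero, so that tables distinguish "no data" from
"no recurrence".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_K",
    "RateSet",
    "NdeDistribution",
    "occurrence_rate",
    "recurrence_rates",
    "rates_to_distribution",
    "distribution_to_rates",
    "mixture_case_composition",
]

#: Default truncation: distributions report P(0..2) and the tail P(>=3+1).
DEFAULT_K = 4

_MASS_TOL = 1e-12


def _check_prob(x: float, name: str) -> float:
    x = float(x)
    if math.isnan(x):
        return x
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")
    return x


@dataclass(frozen=True)
class RateSet:
    """Occurrence rate plus ordered recurrence rates RR(1..k).

    Entries may be NaN where an empirical rate is undefined (empty
    denominator).
    """

    or_: float
    rr: tuple

    def __post_init__(self) -> None:
        _check_prob(self.or_, "OR")
        object.__setattr__(
            self,
            "rr",
            tuple(_check_prob(r, f"RR({i + 1})") for i, r in enumerate(self.rr)),
        )

    def __iter__(self):
        yield self.or_
        yield from self.rr


@dataclass(frozen=True)
class NdeDistribution:
    """P(NDE = 0 .. k-1) plus the tail mass P(NDE >= k)."""

    probabilities: tuple
    tail: float

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probabilities)
        for i, p in enumerate(probs):
            _check_prob(p, f"P({i})")
        _check_prob(self.tail, f"P(>= {len(probs)})")
        total = sum(probs) + self.tail
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"distribution mass sums to {total!r}, not 1")
        object.__setattr__(self, "probabilities", probs)

    @property
    def k(self) -> int:
        return len(self.probabilities)


def occurrence_rate(nde_counts: Sequence[int]) -> float:
    """Fraction of individuals with at least one episode."""
    counts = np.asarray(nde_counts)
    if counts.size == 0:
        raise ValueError("empty episode-count list")
    if np.any(counts < 0):
        raise ValueError("episode counts must be non-negative")
    return float(np.mean(counts >= 1))


def recurrence_rates(nde_counts: Sequence[int], k_max: int) -> RateSet:
    """Empirical OR and RR(1..k_max) from per-individual episode counts.

    ``RR(i) = #{NDE >= i+1} / #{NDE >= i}``; NaN where the denominator
    is zero.
    """
    counts = np.asarray(nde_counts)
    if counts.size == 0:
        raise ValueError("empty episode-count list")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    survival = np.array([(counts >= i).sum() for i in range(0, k_max + 2)])
    rr = []
    for i in range(1, k_max + 1):
        denom = survival[i]
        rr.append(float(survival[i + 1] / denom) if denom > 0 else math.nan)
    return RateSet(or_=float(survival[1] / counts.size), rr=tuple(rr))


def rates_to_distribution(rates: RateSet, k: int = DEFAULT_K) -> NdeDistribution:
    """Closed-form NDE distribution from occurrence and recurrence rates."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(rates.rr) < k - 1:
        raise ValueError(
            f"need RR(1..{k - 1}) for a distribution truncated at k={k}, "
            f"got {len(rates.rr)} recurrence rates"
        )
    if any(math.isnan(r) for r in (rates.or_, *rates.rr[: k - 1])):
        raise ValueError("cannot build a distribution from undefined (NaN) rates")
    probs = [1.0 - rates.or_]
    cum = rates.or_
    for j in range(1, k):
        nxt = cum * rates.rr[j - 1]
        probs.append(cum - nxt)  # == cum * (1 - RR(j))
        cum = nxt
    return NdeDistribution(probabilities=tuple(probs), tail=cum)


def distribution_to_rates(dist: NdeDistribution) -> RateSet:
    """Exact inverse of :func:`rates_to_distribution`."""
    survival = [1.0 - dist.probabilities[0]]  # P(>= 1) = OR
    for p in dist.probabilities[1:]:
        s = survival[-1] - p
        survival.append(0.0 if -_MASS_TOL < s < 0.0 else s)  # rounding guard
    rr = []
    for i in range(len(survival) - 1):
        denom = survival[i]
        rr.append(survival[i + 1] / denom if denom > 0 else math.nan)
    return RateSet(or_=survival[0], rr=tuple(rr))


def mixture_case_composition(
    weights: Sequence[float], ors: Sequence[float]
) -> np.ndarray:
    """Share of affected individuals contributed by each subpopulation.

    ``share_j = w_j OR_j / sum_i w_i OR_i`` -- e.g. mixture weights
    (0.93, 0.07) with subpopulation occurrence rates (0.13, 1.0) give a
    63%/37% split of the individuals who experience at least one episode.
    """
    w = np.asarray(weights, dtype=float)
    o = np.asarray(ors, dtype=float)
    if w.shape != o.shape or w.ndim != 1:
        raise ValueError("weights and ors must be 1-d and of equal length")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    if np.any((o < 0) | (o > 1)):
        raise ValueError("occurrence rates must be in [0, 1]")
    prod = w * o
    total = prod.sum()
    if total <= 0:
        raise ValueError("no affected individuals in any subpopulation")
    return prod / total
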