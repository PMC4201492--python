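"""Named parameter presets, run configuration, file I/O and fixtures.

Presets
-------
``single_population``
    One homogeneous population whose occurrence rate matches the ~20%
    lifetime prevalence of major depressive disorder.
``low_risk`` / ``high_risk``
    The two-subpopulation model: 93% of the population develops depression
    stochastically with low probability (OR = 13%), 7% develops it almost
    surely and runs a chronic course.

All presets share the calibrated noise amplitude and default time step
(see :mod:`moodcourse.dynamics`).

Output files are tidy CSV with a ``#``-prefixed header comment recording
the package version, the configuration hash and the seed, so every file
is traceable to the run that produced it; the companion readers skip
those comments.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, SubpopulationSpec
from .dynamics import ConfigurationError, DynamicsParameters
from .treatment import InterventionSpec

__all__ = [
    "PRESETS",
    "INTERVENTIONS",
    "get_preset",
    "get_intervention",
    "RunConfig",
    "load_config",
    "save_config",
    "generate_sign_fixture",
    "write_table",
    "read_table",
]


def _preset(a, b, c, d, I) -> DynamicsParameters:
    return DynamicsParameters(a=a, b=b, c=c, d=d, I=I)


#: Shipped parameter sets (noise amplitude and dt at package defaults).
PRESETS: Dict[str, DynamicsParameters] = {
    "single_population": _preset(a=4.65, b=-3.0, c=0.175, d=5.0, I=0.02),
    "low_risk": _preset(a=5.0, b=-2.85, c=0.175, d=5.0, I=0.02),
    "high_risk": _preset(a=4.4, b=-3.75, c=0.175, d=4.25, I=0.0),
}

#: Named intervention magnitudes.  These are package conventions chosen to
#: reproduce the directional treatment effects (the underlying studies do
#: not print post-treatment parameter values); override freely in config.
INTERVENTIONS: Dict[str, InterventionSpec] = {
    "ad": InterventionSpec("ad", {"a": 0.2, "b": 0.2}),
    "cbt": InterventionSpec("cbt", {"c": -0.1}),
    "lifestyle": InterventionSpec("lifestyle", {"I": 2.0}),
}


def get_preset(name: str) -> DynamicsParameters:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def get_intervention(name: str) -> InterventionSpec:
    try:
        return INTERVENTIONS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown intervention {name!r}; available: {sorted(INTERVENTIONS)}"
        ) from None


# ---------------------------------------------------------------------------
# Run configuration (YAML / JSON)
# ---------------------------------------------------------------------------

_PARAM_KEYS = {"a", "b", "c", "d", "I", "sigma", "dt"}
_TOP_KEYS = {"seed", "presets", "cohort", "treatment", "output_dir", "log_level"}
_SUBPOP_KEYS = {"name", "weight", "preset", "params", "init_policy"}
_COHORT_KEYS = {"n", "years", "subpopulations"}
_TREATMENT_KEYS = {"intervention", "deltas", "n", "years"}


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def _parse_params(block: dict, context: str) -> DynamicsParameters:
    _reject_unknown(block, _PARAM_KEYS, context)
    missing = {"a", "b", "c", "d"} - set(block)
    if missing:
        raise ConfigurationError(f"{context}: missing parameter(s) {sorted(missing)}")
    return DynamicsParameters(**{k: float(v) for k, v in block.items()})


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    seed: int
    presets: Dict[str, DynamicsParameters] = field(default_factory=dict)
    cohort: Optional[CohortConfig] = None
    treatment: Optional[dict] = None
    output_dir: str = "."
    log_level: str = "INFO"

    def resolve_preset(self, name: str) -> DynamicsParameters:
        if name in self.presets:
            return self.presets[name]
        return get_preset(name)

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed, "output_dir": self.output_dir,
                     "log_level": self.log_level}
        if self.presets:
            out["presets"] = {
                name: {k: getattr(p, k) for k in ("a", "b", "c", "d", "I", "sigma", "dt")}
                for name, p in self.presets.items()
            }
        if self.cohort is not None:
            out["cohort"] = {
                "n": self.cohort.n_individuals,
                "years": self.cohort.duration_days / 365,
                "subpopulations": [
                    {
                        "name": s.name,
                        "weight": s.weight,
                        "params": {
                            k: getattr(s.params, k)
                            for k in ("a", "b", "c", "d", "I", "sigma", "dt")
                        },
                        "init_policy": s.init_policy,
                    }
                    for s in self.cohort.subpopulations
                ],
            }
        if self.treatment is not None:
            out["treatment"] = dict(self.treatment)
        return out


def _parse_config(raw: dict, source: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{source}: config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, source)
    if "seed" not in raw:
        raise ConfigurationError(f"{source}: a 'seed' entry is required")
    seed = int(raw["seed"])

    presets = {
        name: _parse_params(block, f"{source}: presets.{name}")
        for name, block in (raw.get("presets") or {}).items()
    }

    def resolve(name: str) -> DynamicsParameters:
        if name in presets:
            return presets[name]
        return get_preset(name)

    cohort = None
    if "cohort" in raw:
        block = raw["cohort"]
        _reject_unknown(block, _COHORT_KEYS, f"{source}: cohort")
        subs = []
        for j, sub in enumerate(block.get("subpopulations") or []):
            ctx = f"{source}: cohort.subpopulations[{j}]"
            _reject_unknown(sub, _SUBPOP_KEYS, ctx)
            if ("preset" in sub) == ("params" in sub):
                raise ConfigurationError(
                    f"{ctx}: exactly one of 'preset' or 'params' is required"
                )
            params = (
                resolve(sub["preset"])
                if "preset" in sub
                else _parse_params(sub["params"], ctx)
            )
            subs.append(
                SubpopulationSpec(
                    name=sub.get("name", sub.get("preset", f"subpop{j}")),
                    weight=float(sub["weight"]),
                    params=params,
                    init_policy=sub.get("init_policy", "at_positive_fixpoint"),
                )
            )
        if not subs:
            raise ConfigurationError(f"{source}: cohort has no subpopulations")
        cohort = CohortConfig(
            subpopulations=tuple(subs),
            n_individuals=int(block.get("n", 1000)),
            master_seed=seed,
            duration_days=int(round(float(block.get("years", 70)) * 365)),
        )

    treatment = None
    if "treatment" in raw:
        block = raw["treatment"]
        _reject_unknown(block, _TREATMENT_KEYS, f"{source}: treatment")
        if ("intervention" in block) == ("deltas" in block):
            raise ConfigurationError(
                f"{source}: treatment needs exactly one of 'intervention' or 'deltas'"
            )
        treatment = dict(block)

    return RunConfig(
        seed=seed,
        presets=presets,
        cohort=cohort,
        treatment=treatment,
        output_dir=str(raw.get("output_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    return _parse_config(raw, str(path))


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Sign-sequence fixtures
# ---------------------------------------------------------------------------

_SIGN_ALIASES = {
    "neg": True, "symptomatic": True, "-": True,
    "pos": False, "asymptomatic": False, "+": False,
}


def generate_sign_fixture(
    spec: Union[Sequence[Tuple[str, int]], int],
    *,
    n_runs: int = 20,
    mean_length: float = 30.0,
) -> np.ndarray:
    """Daily sign sequence from an explicit run spec or a random seed.

    ``spec`` is either a list of ``(sign, length)`` pairs (sign in
    {'neg', 'pos', 'symptomatic', 'asymptomatic'}), expanded exactly, or an
    integer seed for a random course whose alternating run lengths are
    geometric with the given mean.  Returns a boolean array
    (``True`` = symptomatic day).
    """
    if isinstance(spec, (int, np.integer)):
        rng = np.random.default_rng(int(spec))
        lengths = rng.geometric(1.0 / mean_length, size=n_runs)
        start_symptomatic = bool(rng.integers(2))
        pieces = [
            np.full(int(length), (i % 2 == 0) == start_symptomatic, dtype=bool)
            for i, length in enumerate(lengths)
        ]
        return np.concatenate(pieces)
    pieces = []
    for sign, length in spec:
        if int(length) < 1:
            raise ValueError(f"run length must be >= 1, got {length}")
        key = str(sign).lower()
        if key not in _SIGN_ALIASES:
            raise ValueError(f"unknown sign {sign!r}")
        pieces.append(np.full(int(length), _SIGN_ALIASES[key], dtype=bool))
    if not pieces:
        raise ValueError("empty fixture specification")
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# Tidy CSV with provenance header
# ---------------------------------------------------------------------------

def _config_hash(meta: dict) -> str:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path: Union[str, Path], *,
                seed=None, meta: Optional[dict] = None) -> None:
    """Write a tidy CSV with a provenance comment header."""
    from . import __version__

    meta = dict(meta or {})
    lines = [
        f"# moodcourse {__version__}",
        f"# seed: {seed}",
        f"# config_hash: {_config_hash(meta)}",
    ]
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, comment="#")
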