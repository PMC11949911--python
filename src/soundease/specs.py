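"""Filter parameter registries and min-max (de)normalization.

Two tasks expose two filter palettes:

* **Recollection** — the listener reproduces how a remembered sound felt
  (13 scalar parameters: four peaking amplifiers, additive noise and a
  tinnitus tone, a Butterworth band-reject, reverb, flanger, water effect).
* **Easing** — the listener reshapes the sound until it is tolerable
  (17 parameters: a three-band volume crossover, pitch shift, a dynamic
  change-suppression ducker, a global fader, plus the shared palette).

Every parameter has a declared default and a closed range; models operate on
the unit hypercube via min-max normalization over those ranges, and
predictions are mapped back to native units with the inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "ParamSpec",
    "FilterSpec",
    "FilterSettings",
    "RECOLLECTION",
    "EASING",
    "task_specs",
    "param_keys",
    "default_settings",
    "normalize_settings",
    "denormalize_settings",
    "normalize_ratings",
    "denormalize_ratings",
    "RATING_ITEMS",
]

RATING_ITEMS = ("overall", "painful", "distracting", "anxious", "impeditive")
RATING_MIN, RATING_MAX = 1.0, 7.0


@dataclass(frozen=True)
class ParamSpec:
    name: str
    default: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.lo <= self.default <= self.hi):
            raise ValueError(f"{self.name}: default {self.default} outside [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class FilterSpec:
    """One named filter and its user-adjustable parameters."""

    name: str
    params: Tuple[ParamSpec, ...]

    def param(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(f"{self.name} has no parameter {name!r}")


def _f(name: str, *params: Tuple[str, float, float, float]) -> FilterSpec:
    return FilterSpec(name, tuple(ParamSpec(*p) for p in params))


# Shared palette (identical in both tasks).  Note: the tinnitus amplitude
# default is documented as 0.1 upstream but its own range is 0.0-0.05; the
# registry clamps the default to the range maximum and the discrepancy is
# deliberately surfaced here rather than silently resolved.
_NOISE = _f("noise", ("amplitude", 0.0, 0.0, 0.05))
_TINNITUS = _f("tinnitus", ("amplitude", 0.05, 0.0, 0.05), ("frequency", 1000.0, 20.0, 5000.0))
_BAND_REJECT = _f("band_reject", ("width", 0.1, 0.0, 5000.0), ("center", 1000.0, 20.0, 5000.0))
_ECHO = _f("echo", ("dry_wet", 0.0, 0.0, 1.0))
_FLANGER = _f("flanger", ("power", 0.0, 0.0, 1.0), ("frequency", 0.1, 0.1, 10.0))
_WATER = _f("water", ("gain", 0.0, 0.0, 1.0))

#: Recollection palette, in chain order (13 parameters).
RECOLLECTION: Tuple[FilterSpec, ...] = (
    _f("amplify_all", ("gain", 1.0, 1.0, 5.0)),
    _f("amplify_low", ("gain", 1.0, 1.0, 5.0)),
    _f("amplify_medium", ("gain", 1.0, 1.0, 5.0)),
    _f("amplify_high", ("gain", 1.0, 1.0, 5.0)),
    _NOISE,
    _TINNITUS,
    _BAND_REJECT,
    _ECHO,
    _FLANGER,
    _WATER,
)

#: Easing palette, in chain order (17 parameters).
EASING: Tuple[FilterSpec, ...] = (
    _f("volume_low", ("gain", 1.0, 0.0, 5.0)),
    _f("volume_medium", ("gain", 1.0, 0.0, 5.0)),
    _f("volume_high", ("gain", 1.0, 0.0, 5.0)),
    _f("pitch_shift", ("semitones", 0.0, -12.0, 12.0)),
    _f(
        "change_suppression",
        ("threshold", 0.0015, 0.0, 0.015),
        ("suppression", 1.0, 0.2, 1.0),
        ("back_time", 0.05, 0.05, 10.0),
    ),
    _f("volume_all", ("gain", 1.0, 0.0, 5.0)),
    _NOISE,
    _TINNITUS,
    _BAND_REJECT,
    _ECHO,
    _FLANGER,
    _WATER,
)

_TASKS: Dict[str, Tuple[FilterSpec, ...]] = {"recollection": RECOLLECTION, "easing": EASING}


def task_specs(task: str) -> Tuple[FilterSpec, ...]:
    try:
        return _TASKS[task.lower()]
    except KeyError:
        raise KeyError(f"unknown task {task!r}; expected 'recollection' or 'easing'") from None


def param_keys(task: str) -> List[str]:
    """Ordered flat parameter keys ``<filter>.<param>`` for a task."""
    return [f"{f.name}.{p.name}" for f in task_specs(task) for p in f.params]


def _param_table(task: str) -> Dict[str, ParamSpec]:
    return {f"{f.name}.{p.name}": p for f in task_specs(task) for p in f.params}


@dataclass
class FilterSettings:
    """A complete parameter vector for one task, in native units.

    ``values`` maps flat keys (``"amplify_all.gain"``) to floats; missing keys
    are filled with defaults, unknown keys and out-of-range values are
    rejected.
    """

    task: str
    values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        table = _param_table(self.task)
        unknown = set(self.values) - set(table)
        if unknown:
            raise KeyError(f"unknown parameters for task {self.task!r}: {sorted(unknown)}")
        full: Dict[str, float] = {}
        for key, spec in table.items():
            v = float(self.values.get(key, spec.default))
            if not (spec.lo <= v <= spec.hi):
                raise ValueError(f"{key} = {v} outside range [{spec.lo}, {spec.hi}]")
            full[key] = v
        self.values = full

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def filter_params(self, filter_name: str) -> Dict[str, float]:
        """Parameters of one filter, keyed by bare parameter name."""
        prefix = filter_name + "."
        out = {k[len(prefix):]: v for k, v in self.values.items() if k.startswith(prefix)}
        if not out:
            raise KeyError(f"task {self.task!r} has no filter {filter_name!r}")
        return out

    def is_default(self, key: str, atol: float = 0.0) -> bool:
        spec = _param_table(self.task)[key]
        return abs(self.values[key] - spec.default) <= atol

    def replace(self, **flat_values: float) -> "FilterSettings":
        """New settings with ``filter__param=value`` overrides."""
        merged = dict(self.values)
        for k, v in flat_values.items():
            merged[k.replace("__", ".")] = v
        return FilterSettings(self.task, merged)


def default_settings(task: str) -> FilterSettings:
    return FilterSettings(task, {})


# ---------------------------------------------------------------------------
# Min-max normalization: x_norm = (x - lo) / (hi - lo) over the declared range
# ---------------------------------------------------------------------------

def task_bounds(task: str) -> Tuple[np.ndarray, np.ndarray]:
    table = _param_table(task)
    lo = np.array([table[k].lo for k in param_keys(task)])
    hi = np.array([table[k].hi for k in param_keys(task)])
    return lo, hi


def normalize_settings(settings: FilterSettings) -> np.ndarray:
    """Map native settings onto the unit hypercube (fixed key order)."""
    keys = param_keys(settings.task)
    lo, hi = task_bounds(settings.task)
    x = np.array([settings.values[k] for k in keys])
    return (x - lo) / (hi - lo)


def denormalize_settings(vector: np.ndarray, task: str) -> FilterSettings:
    """Inverse of :func:`normalize_settings`; requires components in [0, 1]."""
    keys = param_keys(task)
    v = np.asarray(vector, dtype=float)
    if v.shape != (len(keys),):
        raise ValueError(f"expected vector of length {len(keys)} for task {task!r}, got {v.shape}")
    if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
        raise ValueError("normalized components must lie in [0, 1]")
    v = np.clip(v, 0.0, 1.0)
    lo, hi = task_bounds(task)
    x = lo + v * (hi - lo)
    return FilterSettings(task, dict(zip(keys, x)))


def normalize_ratings(ratings) -> np.ndarray:
    """Scale 1-7 ratings to [0, 1] (min 1, max 7)."""
    r = np.asarray(ratings, dtype=float)
    if np.any(r < RATING_MIN) or np.any(r > RATING_MAX):
        raise ValueError("ratings must lie in [1, 7]")
    return (r - RATING_MIN) / (RATING_MAX - RATING_MIN)


def denormalize_ratings(unit) -> np.ndarray:
    """Inverse rating scaling back to the continuous 1-7 scale."""
    u = np.asarray(unit, dtype=float)
    return RATING_MIN + np.clip(u, 0.0, 1.0) * (RATING_MAX - RATING_MIN)
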