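"""Parameter and state containers for the three-tier visit model.

The model tracks monthly outpatient visit volumes at China's three
hospital grades: first-level hospitals (FLH, local daily care),
second-level hospitals (SLH, general services) and third-level
hospitals (TLH, severe disease).  Twelve positive constants govern the
dynamics:

* ``r_f, r_s, r_t`` — inherent growth rates of visits per tier
  (per month), i.e. the growth rate at zero load;
* ``m_f, m_s, m_t`` — maximum visit capacities per tier
  (units of 10,000 visits per month), the load at which growth stops;
* ``c_f, c_s, c_t`` — churn rates per tier (per month): fractional
  loss of visits to death or abandoned treatment;
* ``alpha`` — leapfrog rate FLH -> SLH, ``beta`` — SLH -> TLH,
  ``eta`` — FLH -> TLH (per month): fractions of visitors who bypass
  their own tier for a higher one.

Time is measured in months and visit volumes in units of 10,000
monthly visits throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "VisitState",
    "Trajectory",
    "PARAM_NAMES",
    "REFERENCE_PARAMS",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """A parameter value violates the model's positivity constraints."""


PARAM_NAMES: tuple[str, ...] = (
    "r_f", "r_s", "r_t",
    "m_f", "m_s", "m_t",
    "c_f", "c_s", "c_t",
    "alpha", "beta", "eta",
)

_STRICTLY_POSITIVE = ("r_f", "r_s", "r_t", "m_f", "m_s", "m_t", "c_f", "c_s", "c_t")
_NON_NEGATIVE = ("alpha", "beta", "eta")


@dataclass(frozen=True)
class ModelParams:
    """The twelve constants of the visit-dynamics system.

    Growth, capacity and churn parameters must be strictly positive.
    The leapfrog rates ``alpha``, ``beta``, ``eta`` are admitted at
    exactly zero so that decoupled single-tier configurations can be
    expressed (useful for analysis of limiting cases), although in the
    motivating application they are positive.
    """

    r_f: float
    r_s: float
    r_t: float
    m_f: float
    m_s: float
    m_t: float
    c_f: float
    c_s: float
    c_t: float
    alpha: float
    beta: float
    eta: float

    def __post_init__(self) -> None:
        for name in _STRICTLY_POSITIVE:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(
                    f"{name} must be finite and > 0, got {v!r}"
                )
        for name in _NON_NEGATIVE:
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(
                    f"{name} must be finite and >= 0, got {v!r}"
                )

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ModelParams":
        """Build from a mapping with exactly the twelve field names.

        Unknown keys are rejected rather than ignored so that typos in
        config files surface as errors.
        """
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        missing = set(PARAM_NAMES) - set(data)
        if missing:
            raise InvalidParameterError(
                f"missing parameter name(s): {sorted(missing)}"
            )
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_array(self) -> np.ndarray:
        """Parameter vector in the canonical :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "ModelParams":
        if len(vec) != len(PARAM_NAMES):
            raise InvalidParameterError(
                f"expected {len(PARAM_NAMES)} values, got {len(vec)}"
            )
        return cls(**dict(zip(PARAM_NAMES, map(float, vec))))

    def with_(self, **changes: float) -> "ModelParams":
        """Copy with some parameters replaced (validates the result)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class VisitState:
    """Visit volumes ``(x, y, z)`` at the three tiers at one instant.

    ``x`` is the FLH volume, ``y`` the SLH volume and ``z`` the TLH
    volume, all in units of 10,000 visits per month.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidParameterError(
                    f"visit count {name} must be finite and >= 0, got {v!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "VisitState":
        x, y, z = map(float, vec)
        return cls(x, y, z)

    def __iter__(self) -> Iterator[float]:
        return iter((self.x, self.y, self.z))


@dataclass(frozen=True)
class Trajectory:
    """A solution of the system sampled on a time grid.

    ``times`` are months from the start of the run (strictly
    increasing) and ``states`` is an ``(n, 3)`` array of ``(x, y, z)``
    visit volumes, one row per time point.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        if states.shape != (times.size, 3):
            raise ValueError(
                f"states must have shape ({times.size}, 3), got {states.shape}"
            )
        if np.any(states < 0):
            raise ValueError("trajectory states must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    def final_state(self) -> VisitState:
        return VisitState.from_array(self.states[-1])

    def to_frame(self):
        """Return the trajectory as a tidy DataFrame (t, x, y, z)."""
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "x": self.x, "y": self.y, "z": self.z}
        )


#: Parameter values estimated from China's national monthly visit
#: series (January–November, 2011–2018) for the three hospital tiers.
#: Used as the package's reference configuration for simulations and
#: sensitivity sweeps.
REFERENCE_PARAMS = ModelParams(
    r_f=0.0982, r_s=0.1096, r_t=0.0020,
    m_f=9000.1, m_s=29899.2, m_t=42999.8,
    c_f=0.0010, c_s=0.0406, c_t=0.0271,
    alpha=0.044, beta=0.037, eta=0.030,
)
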