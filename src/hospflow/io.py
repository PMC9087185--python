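"""Config parsing, artifact serialisation and run manifests.

All floating-point values are serialised at full precision
(``repr``-round-trippable, 17 significant digits) so that
write-then-read of every artifact reproduces the in-memory values
exactly.  Config documents use strict schemas: unknown keys are
errors, not warnings.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .equilibria import EquilibriumReport
from .fitting import FitResult
from .params import ModelParams, Trajectory, VisitState
from .stability import StabilityReport

__all__ = [
    "ConfigError",
    "RunManifest",
    "write_json",
    "read_json",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "equilibrium_to_dict",
    "stability_to_dict",
    "fit_result_to_dict",
    "validate_keys",
]


class ConfigError(ValueError):
    """A configuration document violates its schema."""


def validate_keys(
    section: Mapping[str, Any], allowed: set[str], where: str
) -> None:
    """Reject unknown keys with an error naming the offending field."""
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with columns t, x, y, z."""
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def trajectory_from_csv(path: str | Path) -> Trajectory:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ConfigError(f"trajectory CSV missing column(s): {sorted(missing)}")
    return Trajectory(
        times=df["t"].to_numpy(), states=df[["x", "y", "z"]].to_numpy()
    )


def equilibrium_to_dict(rep: EquilibriumReport) -> dict[str, Any]:
    return {
        "label": rep.label,
        "exists": rep.exists,
        "point": None if rep.point is None else list(rep.point),
        "conditions": dict(rep.conditions),
        "marginal": rep.marginal,
    }


def stability_to_dict(rep: StabilityReport) -> dict[str, Any]:
    return {
        "label": rep.label,
        "point": list(rep.point),
        "eigenvalues": list(rep.eigenvalues),
        "classification": rep.classification,
        "conditions": dict(rep.conditions),
    }


def fit_result_to_dict(res: FitResult) -> dict[str, Any]:
    return {
        "params": res.params.to_dict(),
        "sse": res.sse,
        "r_squared": res.r_squared,
        "r_squared_per_tier": list(res.r_squared_per_tier),
        "n_obs": res.n_obs,
        "converged": res.converged,
        "initial_state": list(res.initial_state),
        "n_starts": res.n_starts,
        "start_costs": list(res.start_costs),
        "guess_sse": res.guess_sse,
    }


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce it exactly."""

    command: str
    config: dict[str, Any]
    seed: int | None
    version: str
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        write_json(asdict(self), path)


def parse_initial(value: Any, where: str) -> VisitState:
    """Parse an initial state given as [x, y, z] or 'x,y,z'."""
    if isinstance(value, str):
        parts = value.split(",")
    else:
        parts = list(value)
    if len(parts) != 3:
        raise ConfigError(f"{where}: initial state needs exactly 3 components")
    try:
        return VisitState(*(float(v) for v in parts))
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{where}: {err}") from err


def parse_params(section: Mapping[str, Any], where: str) -> ModelParams:
    try:
        return ModelParams.from_dict(section)
    except ValueError as err:
        raise ConfigError(f"{where}: {err}") from err
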