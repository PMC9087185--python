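"""Numerical integration, steady-state detection and parameter sweeps.

Integration uses an adaptive Runge–Kutta 4(5) scheme (``solve_ivp``
with RK45) at tight tolerances (rtol 1e-8, atol 1e-10); the right-hand
side is a smooth quadratic at monthly-scale rates, so stiffness is not
a concern.  States are clipped at zero only within solver tolerance —
the exact system never leaves the non-negative octant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import rhs_array
from .params import PARAM_NAMES, ModelParams, Trajectory, VisitState

__all__ = [
    "integrate",
    "steady_state",
    "sweep",
    "capacity_sweep",
    "SweepResult",
    "IntegrationError",
    "DEFAULT_HORIZON",
    "DEFAULT_INITIAL",
]

#: Default horizon (months) for long-run simulations; long enough for
#: the reference parameter set to settle at its attractor.
DEFAULT_HORIZON = 600.0

#: Fallback initial state when no observed series supplies one.
DEFAULT_INITIAL = VisitState(100.0, 100.0, 100.0)

_RTOL = 1e-8
_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries its diagnostics."""


def integrate(
    params: ModelParams,
    initial: VisitState,
    times: np.ndarray,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Integrate the system and sample it on ``times``.

    ``times`` must be strictly increasing; the first entry is the time
    of the initial condition.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid of >= 2 points")
    sol = solve_ivp(
        lambda _t, s: rhs_array(s, params),
        (times[0], times[-1]),
        initial.to_array(),
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    states = np.maximum(sol.y.T, 0.0)  # clip solver-tolerance undershoots
    return Trajectory(times=times, states=states)


def steady_state(
    params: ModelParams,
    initial: VisitState,
    tol: float = 1e-8,
    t_max: float = 5000.0,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> tuple[VisitState, bool]:
    """Integrate until the vector field is numerically zero.

    Convergence criterion: ``max|rhs| / max(m) < tol``.  Returns the
    final state and a flag saying whether the criterion was met before
    ``t_max`` months.  Non-convergence is signalled by the flag, not an
    exception.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    scale = max(params.m_f, params.m_s, params.m_t)
    state = initial.to_array()
    t = 0.0
    chunk = 200.0
    while t < t_max:
        t_next = min(t + chunk, t_max)
        sol = solve_ivp(
            lambda _t, s: rhs_array(s, params),
            (t, t_next),
            state,
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed: {sol.message}")
        state = np.maximum(sol.y[:, -1], 0.0)
        t = t_next
        if np.max(np.abs(rhs_array(state, params))) / scale < tol:
            return VisitState.from_array(state), True
    return VisitState.from_array(state), False


@dataclass(frozen=True)
class SweepResult:
    """Trajectories of a one-parameter sensitivity sweep.

    All trajectories share the same time grid and initial state; only
    the named parameter varies across ``values``.
    """

    parameter: str
    values: tuple[float, ...]
    trajectories: tuple[Trajectory, ...]
    baseline: ModelParams

    def terminal_states(self) -> np.ndarray:
        """``(n_values, 3)`` array of final states, one row per value."""
        return np.array([tr.states[-1] for tr in self.trajectories])


def sweep(
    params: ModelParams,
    name: str,
    values,
    initial: VisitState | None = None,
    times: np.ndarray | None = None,
) -> SweepResult:
    """Re-integrate the system for each value of one parameter.

    This is the numerical sensitivity experiment: hold eleven
    parameters at their baseline, vary the twelfth over ``values`` and
    compare the resulting trajectories.
    """
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}; expected one of {PARAM_NAMES}")
    if initial is None:
        initial = DEFAULT_INITIAL
    if times is None:
        times = np.linspace(0.0, DEFAULT_HORIZON, 601)
    trajs = tuple(
        integrate(params.with_(**{name: float(v)}), initial, times) for v in values
    )
    return SweepResult(
        parameter=name,
        values=tuple(float(v) for v in values),
        trajectories=trajs,
        baseline=params,
    )


def capacity_sweep(
    params: ModelParams,
    name: str,
    multipliers=(0.5, 1.0, 1.5),
    initial: VisitState | None = None,
    times: np.ndarray | None = None,
) -> SweepResult:
    """Sweep a capacity (or any parameter) over multiples of baseline.

    The conventional capacity experiment uses 0.5x, 1x and 1.5x the
    baseline value of ``m_f``, ``m_s`` or ``m_t``.
    """
    base = getattr(params, name)
    return sweep(
        params, name, [m * base for m in multipliers], initial=initial, times=times
    )
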