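"""Right-hand side of the three-tier visit system and analytic oracles.

The model couples three logistic growth laws through one-way
"leapfrog" transfers (patients choosing a higher tier than their own)
and per-tier churn:

    dx/dt = -(r_f/m_f) x^2 + r_f x - alpha*x - eta*x - c_f*x
    dy/dt = -(r_s/m_s) y^2 + r_s y + alpha*x - beta*y - c_s*y
    dz/dt = -(r_t/m_t) z^2 + r_t z + eta*x + beta*y - c_t*z

The coupling is triangular (feed-forward): x evolves autonomously,
y sees only x, and z sees x and y.  The x-equation is therefore a
scalar logistic equation with an exact closed-form solution, which
this module exposes as an independent oracle for the numerical
integrator.
"""

from __future__ import annotations

import numpy as np

from .params import InvalidParameterError, ModelParams, VisitState

__all__ = ["logistic_rate", "rhs", "rhs_array", "closed_form_x"]


def logistic_rate(v: float, r: float, m: float) -> float:
    """Density-dependent growth rate ``r - (r/m) v``.

    Equals the inherent rate ``r`` at zero load and declines linearly
    to zero when the visit volume ``v`` reaches the capacity ``m``.
    """
    if m <= 0:
        raise InvalidParameterError(f"capacity m must be > 0, got {m!r}")
    return r - (r / m) * v


def rhs_array(state: np.ndarray, p: ModelParams) -> np.ndarray:
    """Vectorised right-hand side on a raw ``(x, y, z)`` array.

    Used internally by the integrator and the fitting residuals where
    constructing :class:`VisitState` objects would be wasteful.
    """
    x, y, z = state
    dx = -(p.r_f / p.m_f) * x * x + p.r_f * x - (p.alpha + p.eta + p.c_f) * x
    dy = -(p.r_s / p.m_s) * y * y + p.r_s * y + p.alpha * x - (p.beta + p.c_s) * y
    dz = -(p.r_t / p.m_t) * z * z + p.r_t * z + p.eta * x + p.beta * y - p.c_t * z
    return np.array([dx, dy, dz])


def rhs(state: VisitState, params: ModelParams) -> tuple[float, float, float]:
    """Time derivatives ``(dx/dt, dy/dt, dz/dt)`` at a state.

    The non-negative octant is forward invariant: each component's
    derivative is non-negative on its own zero face (inflows from
    lower tiers are the only terms that survive).
    """
    d = rhs_array(state.to_array(), params)
    return float(d[0]), float(d[1]), float(d[2])


def closed_form_x(t: float | np.ndarray, x0: float, params: ModelParams):
    """Exact FLH trajectory ``x(t)``, independent of the other tiers.

    The x-equation is scalar logistic with effective linear rate
    ``rho = r_f - alpha - eta - c_f`` and carrying value
    ``K = m_f * rho / r_f``:

        x(t) = K x0 e^{rho t} / (K + x0 (e^{rho t} - 1)),   rho != 0.

    In the degenerate case ``rho = 0`` the equation is separable and
    the solution is ``x(t) = x0 / (1 + (r_f/m_f) x0 t)``.

    Serves as an analytic oracle for the numerical integrator.
    """
    if x0 < 0:
        raise InvalidParameterError(f"x0 must be >= 0, got {x0!r}")
    p = params
    rho = p.r_f - p.alpha - p.eta - p.c_f
    a = p.r_f / p.m_f  # coefficient of the quadratic loss term
    t = np.asarray(t, dtype=float)
    if rho == 0.0:
        out = x0 / (1.0 + a * x0 * t)
    elif x0 == 0.0:
        out = np.zeros_like(t)
    else:
        K = rho / a  # = m_f * rho / r_f; negative when rho < 0
        # Divide through by e^{rho t} when rho*t is large to avoid overflow.
        with np.errstate(over="ignore"):
            e = np.exp(rho * t)
        out = np.where(
            np.isfinite(e),
            K * x0 * e / (K + x0 * (e - 1.0)),
            K,
        )
    out = np.maximum(out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out
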