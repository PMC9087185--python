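"""Closed-form equilibria of the three-tier visit system.

Because the coupling is triangular, the fixed points can be solved
tier by tier.  Four non-negative equilibria arise:

* ``E1 = (0, 0, 0)`` — the empty system; always exists.
* ``E2 = (0, 0, z2)`` — patients only at third-level hospitals;
  exists iff ``H1: r_t > c_t``.
* ``E3 = (0, y3, z3)`` — second- and third-level hospitals occupied;
  exists iff ``H2: r_s > beta + c_s``.
* ``E4 = (x4, y4, z4)`` — all three tiers occupied;
  exists iff ``H3: r_f > alpha + eta + c_f``.

Each non-trivial coordinate is the positive root of a scalar
quadratic: the tier's logistic balance with the transfer inflow from
lower tiers as a constant source.  Existence conditions are strict
inequalities; an exact equality is reported as non-existence with a
``marginal`` flag, since at the boundary the candidate coordinate
collides with a lower equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import rhs_array
from .params import InvalidParameterError, ModelParams, VisitState

__all__ = [
    "EquilibriumReport",
    "existence_conditions",
    "marginal_conditions",
    "positive_root_z",
    "equilibrium_E1",
    "equilibrium_E2",
    "equilibrium_E3",
    "equilibrium_E4",
    "all_equilibria",
]

LABELS = ("E1", "E2", "E3", "E4")


@dataclass(frozen=True)
class EquilibriumReport:
    """One equilibrium: label, coordinates, existence and H-flags.

    When the equilibrium does not exist (its closed form would produce
    a negative coordinate), ``point`` is ``None`` rather than the
    meaningless negative value.  ``marginal`` marks an existence
    condition holding with exact equality.
    """

    label: str
    point: VisitState | None
    exists: bool
    conditions: dict[str, bool] = field(default_factory=dict)
    marginal: bool = False

    def residual(self, params: ModelParams) -> float:
        """Max-norm of the vector field at the point, scaled by capacity."""
        if self.point is None:
            return math.nan
        d = rhs_array(self.point.to_array(), params)
        scale = max(params.m_f, params.m_s, params.m_t)
        return float(max(abs(v) for v in d) / scale)


def existence_conditions(params: ModelParams) -> dict[str, bool]:
    """Evaluate the strict existence inequalities H1–H3.

    * H1: ``r_t > c_t`` (TLH net growth positive at zero load)
    * H2: ``r_s > beta + c_s`` (SLH growth exceeds outflow + churn)
    * H3: ``r_f > alpha + eta + c_f`` (FLH growth exceeds leapfrog + churn)
    """
    p = params
    return {
        "H1": p.r_t > p.c_t,
        "H2": p.r_s > p.beta + p.c_s,
        "H3": p.r_f > p.alpha + p.eta + p.c_f,
    }


def marginal_conditions(params: ModelParams) -> dict[str, bool]:
    """Flag existence conditions that hold with exact equality."""
    p = params
    return {
        "H1": p.r_t == p.c_t,
        "H2": p.r_s == p.beta + p.c_s,
        "H3": p.r_f == p.alpha + p.eta + p.c_f,
    }


def positive_root_z(inflow: float, params: ModelParams) -> float:
    """Unique non-negative TLH volume balancing a constant inflow.

    Solves ``-(r_t/m_t) z^2 + (r_t - c_t) z + inflow = 0`` for its
    non-negative root:

        z = (m_t / 2 r_t) * [(r_t - c_t) + sqrt((r_t - c_t)^2
                                                + 4 r_t inflow / m_t)]

    With zero inflow this reduces to ``max(0, m_t (r_t - c_t) / r_t)``.
    """
    if inflow < 0:
        raise InvalidParameterError(f"inflow must be >= 0, got {inflow!r}")
    p = params
    s = p.r_t - p.c_t
    disc = s * s + 4.0 * p.r_t * inflow / p.m_t
    z = (p.m_t / (2.0 * p.r_t)) * (s + math.sqrt(disc))
    return max(z, 0.0)


def _positive_root_y(inflow: float, params: ModelParams) -> float:
    """Non-negative SLH volume balancing a constant inflow (same quadratic
    structure as :func:`positive_root_z` with the SLH coefficients)."""
    p = params
    s = p.r_s - p.beta - p.c_s
    disc = s * s + 4.0 * p.r_s * inflow / p.m_s
    y = (p.m_s / (2.0 * p.r_s)) * (s + math.sqrt(disc))
    return max(y, 0.0)


def equilibrium_E1(params: ModelParams) -> EquilibriumReport:
    """The trivial equilibrium (0, 0, 0); always exists."""
    return EquilibriumReport(
        label="E1",
        point=VisitState(0.0, 0.0, 0.0),
        exists=True,
        conditions=existence_conditions(params),
    )


def equilibrium_E2(params: ModelParams) -> EquilibriumReport:
    """TLH-only equilibrium ``(0, 0, m_t (r_t - c_t)/r_t)``; needs H1."""
    cond = existence_conditions(params)
    marg = marginal_conditions(params)["H1"]
    if not cond["H1"]:
        return EquilibriumReport("E2", None, False, cond, marginal=marg)
    z = params.m_t * (params.r_t - params.c_t) / params.r_t
    return EquilibriumReport("E2", VisitState(0.0, 0.0, z), True, cond)


def equilibrium_E3(params: ModelParams) -> EquilibriumReport:
    """SLH+TLH equilibrium; needs H2.

    ``y3 = m_s (r_s - beta - c_s)/r_s`` and ``z3`` balances the
    transfer inflow ``beta * y3``.
    """
    cond = existence_conditions(params)
    marg = marginal_conditions(params)["H2"]
    if not cond["H2"]:
        return EquilibriumReport("E3", None, False, cond, marginal=marg)
    p = params
    y = p.m_s * (p.r_s - p.beta - p.c_s) / p.r_s
    z = positive_root_z(p.beta * y, p)
    return EquilibriumReport("E3", VisitState(0.0, y, z), True, cond)


def equilibrium_E4(params: ModelParams) -> EquilibriumReport:
    """Fully occupied equilibrium; needs H3.

    ``x4 = m_f (r_f - alpha - eta - c_f)/r_f``; ``y4`` balances the
    inflow ``alpha * x4``; ``z4`` balances ``eta * x4 + beta * y4``.
    """
    cond = existence_conditions(params)
    marg = marginal_conditions(params)["H3"]
    if not cond["H3"]:
        return EquilibriumReport("E4", None, False, cond, marginal=marg)
    p = params
    x = p.m_f * (p.r_f - p.alpha - p.eta - p.c_f) / p.r_f
    y = _positive_root_y(p.alpha * x, p)
    z = positive_root_z(p.eta * x + p.beta * y, p)
    return EquilibriumReport("E4", VisitState(x, y, z), True, cond)


def all_equilibria(params: ModelParams) -> list[EquilibriumReport]:
    """All four equilibrium reports, E1 first.

    The number of reports with ``exists=True`` is one (E1) plus the
    number of satisfied conditions among H1–H3.
    """
    return [
        equilibrium_E1(params),
        equilibrium_E2(params),
        equilibrium_E3(params),
        equilibrium_E4(params),
    ]
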