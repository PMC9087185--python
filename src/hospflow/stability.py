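"""Local stability of the equilibria via the system Jacobian.

The Jacobian of the triangular system is lower triangular,

    J = [[ -2 r_f x/m_f + r_f - alpha - eta - c_f,  0,  0 ],
         [ alpha,  -2 r_s y/m_s + r_s - beta - c_s,  0 ],
         [ eta,    beta,    -2 r_t z/m_t + r_t - c_t ]],

so its eigenvalues are the (real) diagonal entries and every
equilibrium is classified by their signs alone: all negative ->
locally asymptotically stable, any positive -> unstable, a zero
(within tolerance) -> marginal, no claim made.

The named conditions H4–H7 characterise which equilibrium is the
stable one:

* H4: r_f < alpha+eta+c_f, r_s < beta+c_s, r_t < c_t  ->  E1 stable
* H5: r_f < alpha+eta+c_f, r_s < beta+c_s, r_t > c_t  ->  E2 stable
* H6: r_f < alpha+eta+c_f, r_s > beta+c_s             ->  E3 stable
* H7: r_f > alpha+eta+c_f                              ->  E4 stable

Off the boundary hypersurfaces these four cases partition parameter
space, so exactly one equilibrium is stable for generic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import equilibria as eq
from .params import ModelParams, VisitState

__all__ = [
    "StabilityReport",
    "jacobian",
    "stability_conditions",
    "eigenvalues_at",
    "classify",
    "classify_all",
    "NonexistentEquilibriumError",
]


class NonexistentEquilibriumError(ValueError):
    """Stability was requested at an equilibrium that does not exist."""


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues and sign-based classification at one equilibrium."""

    label: str
    point: VisitState
    eigenvalues: tuple[float, float, float]
    classification: str  # "stable" | "unstable" | "marginal"
    conditions: dict[str, bool] = field(default_factory=dict)


def jacobian(state: VisitState, params: ModelParams) -> np.ndarray:
    """Jacobian of the vector field at a state (lower triangular)."""
    p = params
    x, y, z = state
    return np.array(
        [
            [-2.0 * p.r_f * x / p.m_f + p.r_f - p.alpha - p.eta - p.c_f, 0.0, 0.0],
            [p.alpha, -2.0 * p.r_s * y / p.m_s + p.r_s - p.beta - p.c_s, 0.0],
            [p.eta, p.beta, -2.0 * p.r_t * z / p.m_t + p.r_t - p.c_t],
        ]
    )


def stability_conditions(params: ModelParams) -> dict[str, bool]:
    """Evaluate the mutually exclusive stability conditions H4–H7."""
    p = params
    f_sub = p.r_f < p.alpha + p.eta + p.c_f
    s_sub = p.r_s < p.beta + p.c_s
    return {
        "H4": f_sub and s_sub and p.r_t < p.c_t,
        "H5": f_sub and s_sub and p.r_t > p.c_t,
        "H6": f_sub and p.r_s > p.beta + p.c_s,
        "H7": p.r_f > p.alpha + p.eta + p.c_f,
    }


def _report_for(label: str, params: ModelParams) -> eq.EquilibriumReport:
    getter = {
        "E1": eq.equilibrium_E1,
        "E2": eq.equilibrium_E2,
        "E3": eq.equilibrium_E3,
        "E4": eq.equilibrium_E4,
    }
    if label not in getter:
        raise NonexistentEquilibriumError(f"unknown equilibrium label {label!r}")
    return getter[label](params)


def eigenvalues_at(label: str, params: ModelParams) -> tuple[float, float, float]:
    """Eigenvalues of the Jacobian at a named equilibrium.

    The Jacobian is lower triangular, so these are its diagonal
    entries, in tier order (FLH, SLH, TLH direction).  Raises
    :class:`NonexistentEquilibriumError` if the equilibrium does not
    exist for these parameters.
    """
    rep = _report_for(label, params)
    if not rep.exists:
        raise NonexistentEquilibriumError(
            f"{label} does not exist for these parameters"
        )
    J = jacobian(rep.point, params)
    return (float(J[0, 0]), float(J[1, 1]), float(J[2, 2]))


def _classify_eigs(eigs: tuple[float, float, float], params: ModelParams) -> str:
    # Marginality tolerance tied to the largest rate: the theorems are
    # silent on boundary cases, so a near-zero eigenvalue gets no claim.
    tol = 1e-10 * max(params.r_f, params.r_s, params.r_t)
    if any(abs(e) <= tol for e in eigs):
        return "marginal"
    if all(e < 0 for e in eigs):
        return "stable"
    return "unstable"


def classify(label: str, params: ModelParams) -> StabilityReport:
    """Classify a named equilibrium as stable, unstable or marginal."""
    rep = _report_for(label, params)
    if not rep.exists:
        raise NonexistentEquilibriumError(
            f"{label} does not exist for these parameters"
        )
    eigs = eigenvalues_at(label, params)
    return StabilityReport(
        label=label,
        point=rep.point,
        eigenvalues=eigs,
        classification=_classify_eigs(eigs, params),
        conditions=stability_conditions(params),
    )


def classify_all(params: ModelParams) -> list[StabilityReport]:
    """Stability reports for every equilibrium that exists."""
    return [
        classify(rep.label, params)
        for rep in eq.all_equilibria(params)
        if rep.exists
    ]
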