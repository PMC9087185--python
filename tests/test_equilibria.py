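"""Closed-form equilibria, their existence conditions and consistency."""

import numpy as np
import pytest

from hospflow import (
    ModelParams,
    VisitState,
    all_equilibria,
    equilibrium_E2,
    equilibrium_E3,
    equilibrium_E4,
    existence_conditions,
    positive_root_z,
    steady_state,
)
from hospflow.equilibria import marginal_conditions

from conftest import random_params


def sym_params(**overrides) -> ModelParams:
    base = dict(
        r_f=0.1, r_s=0.1, r_t=0.1, m_f=100.0, m_s=100.0, m_t=100.0,
        c_f=0.05, c_s=0.05, c_t=0.05, alpha=0.0, beta=0.0, eta=0.0,
    )
    base.update(overrides)
    return ModelParams(**base)


class TestExistenceConditions:
    def test_reference_regime(self, ref_params):
        """The national fit sits in the H1-false, H2/H3-true regime."""
        cond = existence_conditions(ref_params)
        assert cond == {"H1": False, "H2": True, "H3": True}

    def test_equality_is_not_existence_but_is_marginal(self):
        p = sym_params(r_t=0.05, c_t=0.05)
        assert existence_conditions(p)["H1"] is False
        assert marginal_conditions(p)["H1"] is True
        assert equilibrium_E2(p).marginal is True

    def test_growth_dominant_regime_satisfies_all(self):
        p = sym_params(r_f=1.0, r_s=1.0, r_t=1.0, c_f=0.001, c_s=0.001,
                       c_t=0.001, alpha=0.01, beta=0.01, eta=0.01)
        assert all(existence_conditions(p).values())


class TestE2:
    def test_closed_form(self):
        p = sym_params(r_t=0.2, c_t=0.1)
        rep = equilibrium_E2(p)
        assert rep.exists
        assert rep.point == VisitState(0.0, 0.0, 50.0)

    def test_reference_params_violate_h1(self, ref_params):
        rep = equilibrium_E2(ref_params)
        assert not rep.exists and rep.point is None

    def test_vanishing_churn_recovers_capacity(self):
        p = sym_params(c_t=1e-12)
        assert equilibrium_E2(p).point.z == pytest.approx(100.0, rel=1e-9)


class TestE3:
    def test_decoupled_when_beta_zero(self):
        p = sym_params(beta=0.0)
        rep = equilibrium_E3(p)
        assert rep.point.y == pytest.approx(100.0 * 0.05 / 0.1)
        # zero inflow and r_t > c_t: z falls back to the E2 level
        assert rep.point.z == pytest.approx(100.0 * 0.05 / 0.1)

    def test_reference_y_coordinate(self, ref_params):
        """y3 = m_s (r_s - beta - c_s) / r_s at the national fit."""
        rep = equilibrium_E3(ref_params)
        assert rep.point.y == pytest.approx(29899.2 * 0.032 / 0.1096, rel=1e-6)
        assert rep.point.y == pytest.approx(8729.7, abs=0.05)

    def test_boundary_is_nonexistence(self):
        p = sym_params(r_s=0.1, beta=0.05, c_s=0.05)
        rep = equilibrium_E3(p)
        assert not rep.exists and rep.marginal


class TestE4:
    def test_three_decoupled_logistic_tiers(self):
        rep = equilibrium_E4(sym_params())
        assert np.allclose(rep.point.to_array(), [50.0, 50.0, 50.0])

    def test_reference_coordinates(self, ref_params):
        """Frozen values computed from the closed form and confirmed by
        long-time integration (see test_agrees_with_integration)."""
        rep = equilibrium_E4(ref_params)
        assert rep.point.x == pytest.approx(2126.2965, abs=1e-3)
        assert rep.point.y == pytest.approx(11041.262, abs=1e-2)
        assert rep.point.z == pytest.approx(18203.322, abs=1e-2)

    def test_continuity_to_decoupled_flh(self):
        p = sym_params(alpha=1e-12, eta=1e-12)
        rep = equilibrium_E4(p)
        assert rep.point.x == pytest.approx(100.0 * 0.05 / 0.1, rel=1e-9)

    def test_x_monotone_in_transfer_rates(self, ref_params):
        """x4 strictly decreases in alpha and eta; beta, m_s, m_t are inert."""
        base = equilibrium_E4(ref_params).point.x
        assert equilibrium_E4(ref_params.with_(alpha=0.05)).point.x < base
        assert equilibrium_E4(ref_params.with_(eta=0.04)).point.x < base
        for change in ({"beta": 0.05}, {"m_s": 50000.0}, {"m_t": 90000.0}):
            assert equilibrium_E4(ref_params.with_(**change)).point.x == base


class TestPositiveRootZ:
    def test_zero_inflow_reduces_to_e2(self):
        p = sym_params(r_t=0.2, c_t=0.1)
        assert positive_root_z(0.0, p) == pytest.approx(50.0)

    def test_zero_inflow_subcritical_gives_zero(self):
        p = sym_params(r_t=0.05, c_t=0.1)
        assert positive_root_z(0.0, p) == 0.0

    def test_reference_inflow(self, ref_params):
        """E4's z solves the TLH quadratic with inflow eta*x4 + beta*y4."""
        rep = equilibrium_E4(ref_params)
        inflow = ref_params.eta * rep.point.x + ref_params.beta * rep.point.y
        assert inflow == pytest.approx(472.3, abs=0.1)
        assert positive_root_z(inflow, ref_params) == pytest.approx(rep.point.z)

    def test_matches_numpy_roots(self, rng):
        """Cross-check against a general polynomial root finder."""
        for _ in range(25):
            p = random_params(rng)
            inflow = rng.uniform(0.0, 0.05 * p.m_t)
            roots = np.roots([-(p.r_t / p.m_t), p.r_t - p.c_t, inflow])
            nonneg = [r.real for r in roots if abs(r.imag) < 1e-12 and r.real >= -1e-9]
            assert positive_root_z(inflow, p) == pytest.approx(
                max(max(nonneg), 0.0), rel=1e-9, abs=1e-9
            )

    def test_rejects_negative_inflow(self, ref_params):
        with pytest.raises(ValueError):
            positive_root_z(-1.0, ref_params)


class TestAllEquilibria:
    def test_count_follows_condition_count(self, rng):
        """One equilibrium per satisfied condition, plus the origin."""
        for _ in range(50):
            p = random_params(rng)
            reports = all_equilibria(p)
            n_existing = sum(r.exists for r in reports)
            n_conditions = sum(existence_conditions(p).values())
            assert n_existing == 1 + n_conditions
            assert reports[0].label == "E1" and reports[0].exists

    def test_reference_set(self, ref_params):
        existing = {r.label for r in all_equilibria(ref_params) if r.exists}
        assert existing == {"E1", "E3", "E4"}

    def test_all_conditions_violated_leaves_only_origin(self):
        p = sym_params(r_f=0.01, r_s=0.01, r_t=0.01)
        existing = [r.label for r in all_equilibria(p) if r.exists]
        assert existing == ["E1"]

    def test_existing_equilibria_are_exact_fixed_points(self, rng):
        for _ in range(50):
            p = random_params(rng)
            for rep in all_equilibria(p):
                if rep.exists:
                    assert rep.residual(p) < 1e-12

    def test_agrees_with_integration(self, rng):
        """The stable closed-form equilibrium is the long-run attractor."""
        from hospflow import classify_all

        n_checked = 0
        while n_checked < 8:
            p = random_params(rng, min_margin=5e-3)
            stable = [r for r in classify_all(p) if r.classification == "stable"]
            assert len(stable) == 1
            target = stable[0].point.to_array()
            start = VisitState(0.02 * p.m_f, 0.02 * p.m_s, 0.02 * p.m_t)
            final, converged = steady_state(p, start, tol=1e-9, t_max=40000.0,
                                            rtol=1e-10, atol=1e-12)
            assert converged
            scale = np.maximum(target, 1e-3 * max(p.m_f, p.m_s, p.m_t))
            assert np.all(np.abs(final.to_array() - target) / scale < 1e-4)
            n_checked += 1
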