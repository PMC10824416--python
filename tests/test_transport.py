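"""Dispersion model and the finite-volume transport step."""

import numpy as np
import pytest
from scipy.special import erfc

from micpsim import (BoundaryConfig, ColumnState, DispersionModel, DomainError,
                     KineticParams, StabilityError, admissible_dt,
                     advance_solutes, dispersion_coefficient,
                     dispersion_tensor, tortuosity)
from micpsim.hydraulics import FlowField


class TestTortuosity:
    def test_exact_values(self):
        assert tortuosity(1.0 - 1e-15) == pytest.approx(1.0)
        assert tortuosity(0.125) == pytest.approx(2.0, rel=1e-12)
        assert tortuosity(0.37) == pytest.approx(1.3933, rel=1e-3)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            tortuosity(bad)


class TestDispersionCoefficient:
    def test_stagnant_fluid_reduces_to_molecular_term(self):
        model = DispersionModel(alpha_l=0.5, d_mol=2e-9)
        # phi^(2/3) * D at v = 0
        assert dispersion_coefficient(0.0, 0.37, model) == pytest.approx(
            1.031e-9, rel=1e-3)

    def test_original_mode_ignores_mechanical_term(self):
        model = DispersionModel(alpha_l=0.5, d_mol=2e-9, mode="original")
        assert model.alpha_l == 0.0
        assert dispersion_coefficient(1e-3, 0.37, model) == pytest.approx(
            dispersion_coefficient(0.0, 0.37, model))

    def test_mechanical_term_dominates_at_bench_velocity(self):
        # half-metre column value of the scaling law with the bench
        # injection velocity: mechanical ~3 orders above molecular
        model = DispersionModel(alpha_l=0.0405, d_mol=2e-9)
        d = dispersion_coefficient(1.885e-4, 0.37, model)
        assert d == pytest.approx(7.64e-6, rel=2e-3)
        assert d / 1.031e-9 > 1e3

    def test_tensor_reduces_to_1d_on_axis(self):
        model = DispersionModel(alpha_l=0.04, alpha_t=0.004, d_mol=2e-9)
        v = 1e-4
        tensor = dispersion_tensor([v, 0.0], 0.37, model)
        assert tensor[0, 0] == pytest.approx(
            dispersion_coefficient(v, 0.37, model), rel=1e-12)
        assert tensor[1, 1] == pytest.approx(
            model.alpha_t * v + 0.37 * tortuosity(0.37) * model.d_mol)
        assert tensor[0, 1] == 0.0


def _uniform_state(n=100, length=1.0, phi=0.37):
    return ColumnState.uniform(length=length, area=1e-3, n_cells=n,
                               phi0=phi, k0=3e-4)


def _flow(state, q):
    q_face = np.full(state.n_cells + 1, q)
    v = q / state.phi
    return FlowField(pressure=np.zeros(state.n_cells), darcy_flux=q_face,
                     pore_velocity=v)


NO_REACT = KineticParams(u_sp=0.0, k_d=0.0, k_att=0.0)


class TestAdvanceSolutes:
    def test_uniform_profile_without_forcing_is_stationary(self):
        state = _uniform_state()
        state.c_urea[:] = 123.0
        model = DispersionModel(alpha_l=0.01)
        advance_solutes(state, _flow(state, 0.0), 1e4, model, NO_REACT)
        assert np.allclose(state.c_urea, 123.0, rtol=1e-14)

    def test_step_front_advects_at_pore_velocity(self):
        state = _uniform_state(n=200, length=1.0)
        state.c_urea[:40] = 100.0  # sharp front at x = 0.2
        model = DispersionModel(alpha_l=0.0, d_mol=0.0)
        q = 1e-4
        flow = _flow(state, q)
        t, target_t = 0.0, 0.3 * state.phi[0] / q  # front travels 0.3 m
        mass0 = state.pore_moles(state.c_urea)
        while t < target_t:
            dt = min(admissible_dt(state, flow, model), target_t - t)
            advance_solutes(state, flow, dt, model, NO_REACT)
            t += dt
        # closed boundaries: total mass exact
        assert state.pore_moles(state.c_urea) == pytest.approx(mass0, rel=1e-12)
        # mid-height of the smeared front within one cell of x = 0.2 + v t
        c = state.c_urea
        idx = np.nonzero(c >= 50.0)[0][-1]
        frac = (c[idx] - 50.0) / (c[idx] - c[idx + 1])
        front = state.x[idx] + frac * state.dx
        assert abs(front - 0.5) <= state.dx

    def test_pure_dispersion_matches_erfc_solution(self):
        # half-saturated column diffusing with constant D*: the analytic
        # solution is C/C0 = 1/2 erfc((x - x_mid)/(2 sqrt(D* t)))
        state = _uniform_state(n=200, length=1.0)
        c0 = 50.0
        state.c_urea[:100] = c0
        model = DispersionModel(alpha_l=0.0, d_mol=4e-6)
        dstar = dispersion_coefficient(0.0, 0.37, model)
        flow = _flow(state, 0.0)
        t, t_end = 0.0, 0.01 / dstar * (0.05 ** 2)  # sigma ~ 0.1 L
        t_end = (0.1 ** 2) / (2 * dstar)
        while t < t_end:
            dt = min(admissible_dt(state, flow, model), t_end - t)
            advance_solutes(state, flow, dt, model, NO_REACT)
            t += dt
        x = state.x
        analytic = 0.5 * c0 * erfc((x - 0.5) / (2.0 * np.sqrt(dstar * t_end)))
        mid = (x > 0.35) & (x < 0.65)
        assert np.max(np.abs(state.c_urea[mid] - analytic[mid])) <= 0.02 * c0
        mid_cell = np.argmin(np.abs(x - 0.5))
        assert state.c_urea[mid_cell] == pytest.approx(analytic[mid_cell],
                                                       rel=0.02)

    def test_closed_boundary_conservation_with_reactions_off(self, rng):
        state = _uniform_state(n=80)
        for arr in (state.c_urea, state.c_ca, state.c_nh4, state.c_bacl):
            arr[:] = rng.uniform(0.0, 200.0, size=80)
        model = DispersionModel(alpha_l=0.02)
        flow = _flow(state, 5e-5)
        masses0 = [state.pore_moles(a) for a in
                   (state.c_urea, state.c_ca, state.c_nh4, state.c_bacl)]
        for _ in range(50):
            dt = admissible_dt(state, flow, model)
            advance_solutes(state, flow, dt, model, NO_REACT)
        masses = [state.pore_moles(a) for a in
                  (state.c_urea, state.c_ca, state.c_nh4, state.c_bacl)]
        for m0, m1 in zip(masses0, masses):
            assert m1 == pytest.approx(m0, rel=1e-10)

    def test_reaction_stoichiometry_cellwise(self):
        # no transport: every change comes from ureolysis, cell by cell
        state = _uniform_state(n=30)
        state.c_urea[:] = 300.0
        state.c_ca[:] = np.linspace(0.0, 100.0, 30)
        state.c_bacl[:] = 1e6
        before = (state.c_urea.copy(), state.c_ca.copy(), state.c_nh4.copy())
        model = DispersionModel(alpha_l=0.0, d_mol=0.0)
        report = advance_solutes(state, _flow(state, 0.0), 500.0, model,
                                 KineticParams())
        d_urea = before[0] - state.c_urea
        d_ca = before[1] - state.c_ca
        d_nh4 = state.c_nh4 - before[2]
        assert np.allclose(d_urea, d_ca, rtol=0.0, atol=1e-12)
        assert np.allclose(d_nh4, 2.0 * d_urea, rtol=0.0, atol=1e-12)
        assert np.allclose(report.urea_converted, d_urea, atol=1e-12)
        # cells with no calcium react not at all
        assert d_urea[0] == 0.0

    def test_reaction_clipping_keeps_fields_nonnegative(self):
        state = _uniform_state(n=10)
        state.c_urea[:] = 5.0
        state.c_ca[:] = 2.0
        state.c_bacl[:] = 1e9  # absurdly reactive
        model = DispersionModel(alpha_l=0.0, d_mol=0.0)
        advance_solutes(state, _flow(state, 0.0), 1e4, model, KineticParams())
        assert np.all(state.c_ca >= 0.0) and np.all(state.c_urea >= 0.0)
        assert np.allclose(state.c_ca, 0.0)          # calcium exhausted
        assert np.allclose(state.c_urea, 3.0)        # one-for-one with Ca

    def test_dirichlet_inflow_reaches_injected_concentration(self):
        state = _uniform_state(n=60, length=0.3)
        model = DispersionModel(alpha_l=0.005)
        bc = BoundaryConfig(rate=1e-7, source_end="bottom",
                            injected={"urea": 300.0})
        q = bc.rate / state.area
        flow = _flow(state, q)
        t = 0.0
        while t < 0.5 * state.length * state.phi[0] / q:
            dt = admissible_dt(state, flow, model)
            advance_solutes(state, flow, dt, model, NO_REACT, bc=bc)
            t += dt
        assert state.c_urea[0] == pytest.approx(300.0, rel=0.05)
        # the far end sees only the faint dispersive tail (< 1% of C0)
        assert state.c_urea[-1] < 3.0
        # species absent from the injection enter with zero flux
        assert np.all(state.c_ca == 0.0)

    def test_overlarge_step_refused_with_admissible_value(self):
        state = _uniform_state()
        model = DispersionModel(alpha_l=0.01)
        flow = _flow(state, 1e-4)
        dt_adm = admissible_dt(state, flow, model)
        with pytest.raises(StabilityError) as err:
            advance_solutes(state, flow, 10.0 * dt_adm, model, NO_REACT)
        assert err.value.admissible_dt == pytest.approx(dt_adm)

    def test_positivity_near_stability_bound(self):
        state = _uniform_state(n=50)
        state.c_urea[10:12] = 500.0  # isolated spike
        model = DispersionModel(alpha_l=0.03)
        flow = _flow(state, 2e-4)
        for _ in range(200):
            dt = admissible_dt(state, flow, model)
            advance_solutes(state, flow, dt, model, NO_REACT)
        assert np.all(state.c_urea >= 0.0)
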