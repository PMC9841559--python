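"""Phase-space propagator: thermal states, conservation laws, rates."""

import dataclasses

import numpy as np
import pytest

import tautodyn as td
from tautodyn import pes, wigner as wg
from tautodyn.errors import (
    DomainError,
    InvalidWellError,
    NonConvergenceError,
    ParameterError,
    StabilityError,
)
from tautodyn.units import HBAR, KB

from conftest import harmonic_profile

T_REF = 650.0
WEAK_BATH = wg.BathSpec(gamma_cm=100.0, T_tilde=T_REF)


def _free_profile(half_width=6.0):
    s = np.linspace(-half_width, half_width, 101)
    return pes.interpolate(pes.ReactionPath(s=s, energy=np.zeros_like(s)))


def _gaussian_state(grid, q0, p0, sq, sp):
    Q, P = np.meshgrid(grid.q, grid.p, indexing="ij")
    W = np.exp(-((Q - q0) ** 2) / (2 * sq**2) - ((P - p0) ** 2) / (2 * sp**2))
    return wg.WignerState(W, grid).normalized()


class TestThermalState:
    def test_gaussian_matches_harmonic_closed_form(self, hydrogen):
        omega = 0.08
        prof = harmonic_profile(omega, hydrogen, half_width=3.0)
        T = 298.0
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, T, pad_q=0.0)
        st = wg.thermal_initial_state(
            prof, (-3.0, 3.0), hydrogen, T, method="gaussian", grid=grid
        )
        var_q, var_p = wg.harmonic_thermal_variances(omega, hydrogen, T)
        assert st.norm() == pytest.approx(1.0, abs=1e-9)
        assert st.var_q() == pytest.approx(var_q, rel=1e-3)
        assert st.var_p() == pytest.approx(var_p, rel=1e-3)

    def test_classical_mode_recovers_boltzmann_widths(self, hydrogen):
        omega = 0.08
        prof = harmonic_profile(omega, hydrogen, half_width=3.0)
        T = 298.0
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, T, pad_q=0.0)
        st = wg.thermal_initial_state(
            prof, (-3.0, 3.0), hydrogen, T, method="gaussian", grid=grid,
            mode="classical",
        )
        assert st.var_p() == pytest.approx(hydrogen.mass * KB * T, rel=1e-3)
        # the quantum widths are strictly larger (zero-point motion)
        _, var_p_q = wg.harmonic_thermal_variances(omega, hydrogen, T)
        assert var_p_q > hydrogen.mass * KB * T

    def test_eigen_state_localized_in_well(self, hydrogen):
        # asymmetric double well; >=99.9% of the density stays on the
        # reactant side of the transition state
        s = np.linspace(-2.5, 2.5, 201)
        e = 0.3 * (1 - (s / 1.5) ** 2) ** 2 + 0.02 * s
        prof = pes.interpolate(pes.ReactionPath(s=s, energy=e - e[0]))
        bs = td.barrier_summary(prof)
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 298.0, pad_q=0.0)
        st = wg.thermal_initial_state(
            prof, (-2.5, bs.s_TS), hydrogen, 298.0, method="eigen", grid=grid
        )
        inside = st.W[grid.q < bs.s_TS].sum() * grid.dq * grid.dp
        assert st.norm() == pytest.approx(1.0, abs=1e-9)
        assert inside > 0.999

    def test_eigen_and_gaussian_agree_on_harmonic_well(self, hydrogen):
        omega = 0.1
        prof = harmonic_profile(omega, hydrogen, half_width=3.0)
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 400.0, pad_q=0.0)
        st_e = wg.thermal_initial_state(
            prof, (-3.0, 3.0), hydrogen, 400.0, method="eigen", grid=grid
        )
        st_g = wg.thermal_initial_state(
            prof, (-3.0, 3.0), hydrogen, 400.0, method="gaussian", grid=grid
        )
        assert st_e.var_p() == pytest.approx(st_g.var_p(), rel=5e-3)
        assert st_e.var_q() == pytest.approx(st_g.var_q(), rel=5e-3)

    def test_gaussian_requires_interior_minimum(self, hydrogen):
        prof = _free_profile()
        with pytest.raises(InvalidWellError):
            wg.thermal_initial_state(
                prof, (-2.0, 2.0), hydrogen, 300.0, method="gaussian"
            )


class TestPropagation:
    def test_free_streaming_drifts_at_p_over_mu(self, hydrogen):
        prof = _free_profile()
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 300.0, pad_q=0.0)
        p0 = 2.0
        st = _gaussian_state(grid, -2.0, p0, 0.3, 0.5)
        bath = wg.BathSpec(gamma_cm=0.0, T_tilde=300.0)
        cfg = wg.PropagatorConfig(
            dt=0.2, boundary="reflecting", pad_q=0.0, wall_height=0.0
        )
        mp_before = st.marginal_p()
        out = wg.propagate(st, prof, hydrogen, bath, cfg, 60.0)
        assert out.mean_q() == pytest.approx(-2.0 + p0 / hydrogen.mass * 60.0, abs=1e-3)
        np.testing.assert_allclose(out.marginal_p(), mp_before, atol=1e-9)

    def test_ehrenfest_relation_in_harmonic_well(self, hydrogen):
        omega = 0.06
        prof = harmonic_profile(omega, hydrogen, half_width=4.0)
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 300.0, pad_q=0.0)
        st = _gaussian_state(grid, 1.0, 0.0, 0.25, 1.2)
        bath = wg.BathSpec(gamma_cm=0.0, T_tilde=300.0)
        cfg = wg.PropagatorConfig(
            dt=0.1, boundary="reflecting", pad_q=0.0, wall_height=0.0
        )
        prop = wg.Propagator(prof, hydrogen, bath, cfg, grid=grid)
        qs, ps, ts = [], [], []

        def cb(istep, t, W):
            s = wg.WignerState(W, grid, t)
            qs.append(s.mean_q())
            ps.append(s.mean_p())
            ts.append(t)

        prop.run(st, 40.0, callback=cb, sample_every=1)
        dq_dt = np.gradient(np.asarray(qs), np.asarray(ts))
        np.testing.assert_allclose(
            dq_dt[2:-2], np.asarray(ps)[2:-2] / hydrogen.mass, atol=2e-3
        )

    def test_norm_conserved_in_closed_system(self, eckart_profile, hydrogen):
        bath = wg.BathSpec(gamma_cm=0.0, T_tilde=T_REF)
        cfg = wg.PropagatorConfig(dt=0.25, n_q=128, n_p=128, boundary="reflecting")
        grid = wg.PhaseSpaceGrid.for_profile(
            eckart_profile, hydrogen, T_REF, n_q=128, n_p=128, pad_q=1.0
        )
        bs = td.barrier_summary(eckart_profile)
        prop = wg.Propagator(eckart_profile, hydrogen, bath, cfg, grid=grid)
        st = wg.thermal_initial_state(
            eckart_profile, (float(grid.q[0]), bs.s_TS), hydrogen, T_REF,
            grid=grid, potential=prop.extended_V,
        )
        out = prop.run(st, 0.25 * 300)
        assert abs(out.norm() - 1.0) < 1e-6

    def test_quantum_equals_classical_on_harmonic(self, hydrogen):
        # Moyal corrections vanish identically for quadratic potentials
        prof = harmonic_profile(0.08, hydrogen, half_width=4.0)
        grid = wg.PhaseSpaceGrid.for_profile(
            prof, hydrogen, 400.0, n_q=128, n_p=128, pad_q=0.0
        )
        st = _gaussian_state(grid, 0.8, 0.0, 0.3, 1.5)
        bath = wg.BathSpec(gamma_cm=300.0, T_tilde=400.0)
        base = wg.PropagatorConfig(
            dt=0.2, n_q=128, n_p=128, boundary="reflecting", pad_q=0.0,
            wall_height=0.0,
        )
        out_q = wg.propagate(st, prof, hydrogen, bath, base, 100.0)
        out_c = wg.propagate(
            st, prof, hydrogen, bath,
            dataclasses.replace(base, mode="classical"), 100.0,
        )
        assert np.abs(out_q.W - out_c.W).max() < 1e-8

    def test_momentum_variance_reaches_bath_temperature(self, hydrogen):
        # fluctuation-dissipation: stationary Var(p) = mu kB T_tilde in the
        # high-temperature harmonic well (kB T >> hbar omega)
        omega = 0.05
        T = 1500.0
        prof = harmonic_profile(omega, hydrogen, half_width=4.0)
        assert KB * T / (HBAR * omega) > 3.0
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, T, pad_q=0.0)
        st = wg.thermal_initial_state(
            prof, (-4.0, 4.0), hydrogen, T, method="gaussian", grid=grid
        )
        bath = wg.BathSpec(gamma_cm=600.0, T_tilde=T)
        cfg = wg.PropagatorConfig(
            dt=0.1, boundary="reflecting", pad_q=0.0, wall_height=0.0
        )
        out = wg.propagate(st, prof, hydrogen, bath, cfg, 300.0)
        assert out.var_p() == pytest.approx(hydrogen.mass * KB * T, rel=0.02)


class TestFlux:
    def test_even_state_has_zero_flux(self, hydrogen):
        prof = _free_profile()
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 300.0, pad_q=0.0)
        st = _gaussian_state(grid, 0.0, 0.0, 0.4, 1.0)
        assert abs(wg.transition_state_flux(st, hydrogen, 0.0)) < 1e-12

    def test_drifting_gaussian_flux_closed_form(self, hydrogen):
        prof = _free_profile()
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 300.0, pad_q=0.0)
        p0 = 2.0
        st = _gaussian_state(grid, 0.0, p0, 0.4, 0.3)
        J = wg.transition_state_flux(st, hydrogen, 0.0)
        marginal = st.marginal_q()[np.searchsorted(grid.q, 0.0)]
        assert J == pytest.approx(p0 / hydrogen.mass * marginal, rel=1e-6)

    def test_dividing_surface_outside_grid_rejected(self, hydrogen):
        prof = _free_profile()
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 300.0, pad_q=0.0)
        st = _gaussian_state(grid, 0.0, 0.0, 0.4, 1.0)
        with pytest.raises(DomainError):
            wg.transition_state_flux(st, hydrogen, 50.0)


class TestGuards:
    def test_oversized_timestep_rejected(self, eckart_profile, hydrogen):
        bath = wg.BathSpec(gamma_cm=100.0, T_tilde=650.0)
        cfg = wg.PropagatorConfig(dt=500.0, n_q=64, n_p=64)
        with pytest.raises(StabilityError):
            wg.Propagator(eckart_profile, hydrogen, bath, cfg)

    def test_no_plateau_raises_with_partial_series(self, eckart_profile, hydrogen):
        cfg = wg.PropagatorConfig(dt=0.25, n_q=64, n_p=64, max_time=120.0)
        with pytest.raises(NonConvergenceError) as err:
            wg.compute_rate(eckart_profile, hydrogen, WEAK_BATH, cfg, T_REF)
        assert err.value.partial is not None
        assert err.value.partial.times.size > 0

    def test_classical_mode_forces_first_order(self):
        cfg = wg.PropagatorConfig(mode="classical", moyal_order=3)
        assert cfg.effective_order == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            wg.PropagatorConfig(scheme="magic")
        with pytest.raises(ParameterError):
            wg.PropagatorConfig(moyal_order=2)
        with pytest.raises(ParameterError):
            wg.ParticleSpec.from_isotope("T")


class TestRateMachinery:
    def test_kappa_identity_between_identical_modes(self, eckart_profile, hydrogen):
        # both modes at first order are the same operator: kappa == 1 exactly
        cfg = wg.PropagatorConfig(
            dt=0.5, n_q=96, n_p=96, max_time=4000.0, moyal_order=1
        )
        res = wg.kappa(eckart_profile, hydrogen, WEAK_BATH, cfg, T_REF)
        assert res.kappa == pytest.approx(1.0, abs=1e-12)

    def test_grid_refinement_converges_kappa(self, eckart_profile, hydrogen):
        # halving dq, dp and dt changes kappa by < 2%
        coarse = wg.PropagatorConfig(dt=0.5, n_q=128, n_p=128, max_time=6000.0)
        fine = wg.PropagatorConfig(dt=0.25, n_q=256, n_p=256, max_time=6000.0)
        k_c = wg.kappa(eckart_profile, hydrogen, WEAK_BATH, coarse, T_REF).kappa
        k_f = wg.kappa(eckart_profile, hydrogen, WEAK_BATH, fine, T_REF).kappa
        assert abs(k_f - k_c) / k_c < 0.02

    def test_checkpoint_roundtrip(self, hydrogen, tmp_path):
        prof = _free_profile()
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 300.0, pad_q=0.0)
        st = _gaussian_state(grid, 0.5, 1.0, 0.4, 1.0)
        st.time = 12.5
        f = tmp_path / "state.npz"
        wg.save_state(st, f)
        back = wg.load_state(f)
        assert back.time == 12.5
        np.testing.assert_array_equal(back.W, st.W)
        np.testing.assert_array_equal(back.grid.q, grid.q)

    def test_propagation_log_records(self, hydrogen, tmp_path):
        prof = _free_profile()
        grid = wg.PhaseSpaceGrid.for_profile(prof, hydrogen, 300.0, pad_q=0.0)
        st = _gaussian_state(grid, -2.0, 2.0, 0.3, 0.5)
        bath = wg.BathSpec(gamma_cm=0.0, T_tilde=300.0)
        cfg = wg.PropagatorConfig(
            dt=0.2, boundary="reflecting", pad_q=0.0, wall_height=0.0
        )
        log = tmp_path / "run.tsv"
        wg.propagate(st, prof, hydrogen, bath, cfg, 10.0, log_file=log, s_div=0.0)
        lines = log.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["t_fs", "norm", "mean_q", "mean_p", "flux"]
        assert len(lines) > 3
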