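import numpy as np
import pytest

from tumorcal.forward_models import (
    Grid,
    PhaseFieldParams,
    PhaseFieldState,
    ReducedParams,
    chemical_potential,
    degraded_mobility,
    double_well,
    double_well_prime,
    exponential_death_exact,
    logistic_growth_exact,
    necrosis_no_nutrient_exact,
    simulate_exponential_death,
    simulate_full_phase_field,
    simulate_logistic_growth,
    simulate_mobility_ch,
    simulate_necrosis_system,
    split_contractive_expansive,
    total_free_energy,
)

DAYS = np.arange(0.0, 8.0)


class TestEnergyPrimitives:
    def test_double_well_pure_phases_and_barrier(self):
        assert double_well(0.0, 0.65) == 0.0
        assert double_well(1.0, 0.65) == 0.0
        assert double_well(0.5, 0.65) == pytest.approx(0.65 / 16)
        assert double_well_prime(0.5, 0.65) == pytest.approx(0.0)

    def test_splitting_is_an_identity(self):
        phi = np.linspace(-0.5, 1.5, 1000)
        psi_c, psi_e = split_contractive_expansive(phi, 0.65)
        np.testing.assert_allclose(psi_c - psi_e, double_well(phi, 0.65), atol=1e-14)

    def test_degraded_mobility_limits(self):
        phi_t = np.array([[0.0, 0.5], [0.8, 0.3]])
        phi_n = np.array([[0.0, 0.0], [0.8, 0.15]])
        mob = degraded_mobility(phi_t, phi_n, 200.0)
        assert mob[0, 0] == 200.0  # no tumor: full mobility by convention
        assert mob[0, 1] == 200.0  # no necrosis
        assert mob[1, 0] == 0.0  # fully necrotic
        assert mob[1, 1] == pytest.approx(100.0)
        with pytest.raises(ValueError):
            degraded_mobility(np.array([[0.1]]), np.array([[0.2]]), 1.0)

    def test_chemical_potential_uniform_fields(self, grid64):
        for phi, mu_want in [(0.0, 0.0), (0.5, 0.0), (1.0, 0.0), (0.25, 0.1875 * 0.65)]:
            field = np.full(grid64.shape, phi)
            mu = chemical_potential(field, 0.65, 30.0, grid64)
            np.testing.assert_allclose(mu, mu_want, atol=1e-12)

    def test_chemical_potential_linearization(self):
        # mu of a small cosine mode about phi=0.5: (Psi''(0.5) + eps^2 k^2) a cos(kx)
        grid = Grid(nx=64, ny=8, spacing=1.0)
        e_bar, eps, a = 0.65, 3.0, 1e-4
        k = 2 * np.pi / grid.nx
        x = (np.arange(grid.nx) + 0.5) * grid.spacing
        phi = 0.5 + a * np.cos(k * x)[None, :] * np.ones((grid.ny, 1))
        mu = chemical_potential(phi, e_bar, eps, grid, bc="periodic")
        psi_pp = e_bar * (2 - 12 * 0.5 + 12 * 0.25)  # Psi'' at 1/2 = -E
        k_disc = 2.0 * (1 - np.cos(k))  # discrete Laplacian symbol
        expected = a * (psi_pp + eps**2 * k_disc) * np.cos(k * x)
        np.testing.assert_allclose(mu[0], expected, atol=a * 1e-6)

    def test_total_free_energy_closed_forms(self, grid64):
        area = grid64.n_cells * grid64.cell_area
        assert total_free_energy(np.zeros(grid64.shape), 0.65, 30.0, grid64) == 0.0
        e = total_free_energy(np.full(grid64.shape, 0.5), 0.65, 30.0, grid64)
        assert e == pytest.approx(0.65 / 16 * area)
        rng = np.random.default_rng(1)
        assert total_free_energy(rng.uniform(0, 1, grid64.shape), 0.65, 30.0, grid64) >= 0


class TestReducedModels:
    def test_exponential_closed_form_value(self):
        p = ReducedParams(lambda_apop=0.11, phi_V0=8.44e-2)
        end = exponential_death_exact(p, np.array([0.0, 7.0]))[-1]
        assert end == pytest.approx(8.44e-2 * np.exp(-0.77), rel=1e-14)

    def test_rk4_matches_exponential(self):
        p = ReducedParams(lambda_apop=0.11, phi_V0=8.44e-2)
        rk = simulate_exponential_death(p, DAYS, dt=0.01).phi_V
        ex = exponential_death_exact(p, DAYS)
        np.testing.assert_allclose(rk, ex, rtol=1e-8)

    def test_zero_rate_is_constant(self):
        p = ReducedParams(lambda_apop=0.0, phi_V0=0.05)
        assert np.all(simulate_exponential_death(p, DAYS).phi_V == 0.05)

    def test_rk4_matches_logistic_closed_form(self):
        p = ReducedParams(lambda_prol=0.5, lambda_apop=0.1, K=0.14,
                          phi_sigma=1.0, phi_V0=0.01)
        rk = simulate_logistic_growth(p, DAYS, dt=0.01).phi_V
        ex = logistic_growth_exact(p, DAYS)
        np.testing.assert_allclose(rk, ex, rtol=1e-6)
        # closed form sanity: r = 0.4, K_eff = 0.112
        assert ex[-1] == pytest.approx(
            0.112 / (1 + (0.112 / 0.01 - 1) * np.exp(-0.4 * 7)), rel=1e-12
        )

    def test_logistic_textbook_limit(self):
        p = ReducedParams(lambda_prol=1.0, lambda_apop=0.0, K=0.14,
                          phi_sigma=1.0, phi_V0=0.01)
        traj = simulate_logistic_growth(p, np.linspace(0, 40, 11)).phi_V
        assert traj[-1] == pytest.approx(0.14, rel=1e-4)
        assert np.all(np.diff(traj) >= 0)  # saturates exactly at K in float
        assert np.all(np.diff(traj[:4]) > 0)

    def test_logistic_balanced_rates_decay(self):
        # lambda_prol * phi_sigma == lambda_apop: algebraic decay toward 0
        p = ReducedParams(lambda_prol=0.4, lambda_apop=0.2, K=0.14,
                          phi_sigma=0.5, phi_V0=0.05)
        ex = logistic_growth_exact(p, DAYS)
        rk = simulate_logistic_growth(p, DAYS, dt=0.01).phi_V
        np.testing.assert_allclose(rk, ex, rtol=1e-6)
        assert np.all(np.diff(ex) < 0) and ex[-1] > 0

    def test_necrosis_zero_nutrient_closed_form(self):
        p = ReducedParams(lambda_prol=0.5, lambda_apop=0.09, lambda_VN=0.11,
                          K=0.14, phi_sigma=0.0, phi_V0=0.0422)
        rk = simulate_necrosis_system(p, DAYS, dt=0.01)
        ex = necrosis_no_nutrient_exact(p, DAYS)
        np.testing.assert_allclose(rk.values, ex, rtol=1e-6)
        # phi_V decays at the combined rate lambda_apop + lambda_VN
        np.testing.assert_allclose(
            rk.column("phi_V"), 0.0422 * np.exp(-0.2 * DAYS), rtol=1e-6
        )

    def test_necrosis_reduces_to_logistic_without_transfer(self):
        p = ReducedParams(lambda_prol=0.5, lambda_apop=0.09, lambda_VN=0.0,
                          K=0.14, phi_sigma=1.0, phi_V0=0.01)
        nec = simulate_necrosis_system(p, DAYS, dt=0.01)
        assert np.all(nec.column("phi_N") == 0.0)
        np.testing.assert_allclose(
            nec.column("phi_V"), logistic_growth_exact(p, DAYS), rtol=1e-6
        )

    def test_necrotic_core_never_decreases(self, reduced_params):
        for phi_sigma in (0.0, 0.5, 1.0):
            p = ReducedParams(lambda_prol=0.5, lambda_apop=0.09, lambda_VN=0.11,
                              K=0.14, phi_sigma=phi_sigma, phi_V0=0.0422)
            nec = simulate_necrosis_system(p, DAYS)
            assert np.all(np.diff(nec.column("phi_N")) >= 0)
            assert np.all(nec.column("phi_N") <= nec.column("phi_T") + 1e-6)

    def test_rk4_step_refinement_fourth_order(self):
        p = ReducedParams(lambda_prol=0.5, lambda_apop=0.1, K=0.14,
                          phi_sigma=1.0, phi_V0=0.01)
        ex = logistic_growth_exact(p, np.array([0.0, 7.0]))[-1]
        errs = []
        for dt in (0.2, 0.1):
            rk = simulate_logistic_growth(p, np.array([0.0, 7.0]), dt=dt).phi_V[-1]
            errs.append(abs(rk - ex))
        assert errs[1] < errs[0] / 8  # ~16x for a 4th-order method

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ReducedParams(lambda_apop=-0.1)
        with pytest.raises(ValueError):
            ReducedParams(K=0.0)
        with pytest.raises(ValueError):
            ReducedParams(phi_V0=0.9, phi_N0=0.2)


class TestMobilityCH:
    def test_uniform_field_is_fixed_point(self, grid64, pf_params):
        state = PhaseFieldState(np.full(grid64.shape, 0.3), np.zeros(grid64.shape))
        traj = simulate_mobility_ch(pf_params, state, np.linspace(0, 0.25, 6), grid64)
        for s in traj.states:
            np.testing.assert_allclose(s.phi_T, 0.3, atol=1e-12)

    def test_zero_mobility_freezes_field(self, grid64, clustered_state):
        params = PhaseFieldParams(M_T=0.0, E_bar_T=0.65, epsilon_T=30.0)
        traj = simulate_mobility_ch(params, clustered_state, [0.0, 0.25, 0.5], grid64)
        np.testing.assert_array_equal(traj.states[-1].phi_T, clustered_state.phi_T)

    def test_mass_conserved_and_energy_decays(self, grid64, pf_params, clustered_state):
        # one output per solver step so the energy check sees every step
        times = np.linspace(0.0, 0.5, 101)
        traj = simulate_mobility_ch(pf_params, clustered_state, times, grid64, dt=0.005)
        masses = np.array([s.phi_T.sum() * grid64.cell_area for s in traj.states])
        assert np.max(np.abs(masses - masses[0]) / masses[0]) <= 1e-10
        energies = np.array([
            total_free_energy(s.phi_T, pf_params.E_bar_T, pf_params.epsilon_T, grid64)
            for s in traj.states
        ])
        assert np.all(np.diff(energies) <= 1e-10 * np.abs(energies[:-1]))

    def test_linear_mode_decay_rate(self):
        # about phi=0: d(ln a)/dt = -M k^2 (Psi''(0) + eps^2 k^2), periodic domain
        grid = Grid(nx=64, ny=8, spacing=1.0)
        m_t, e_bar, eps = 0.5, 0.65, 2.0
        params = PhaseFieldParams(M_T=m_t, E_bar_T=e_bar, epsilon_T=eps)
        k = 2 * np.pi * 2 / grid.nx
        x = (np.arange(grid.nx) + 0.5) * grid.spacing
        a0 = 1e-4
        phi0 = 0.5 + a0 * np.cos(k * x)[None, :] * np.ones((grid.ny, 1))
        state = PhaseFieldState(phi0, np.zeros(grid.shape))
        t_end = 0.01
        traj = simulate_mobility_ch(params, state, [0.0, t_end], grid,
                                    dt=1e-5, bc="periodic", bound_tol=1.0)
        amp = (traj.states[-1].phi_T[0] * np.cos(k * x)).sum() * 2 / grid.nx
        k2 = 2.0 * (1 - np.cos(k))  # discrete symbol of k^2
        rate = m_t * k2 * (e_bar * (2 - 12 * 0.5 + 12 * 0.25) + eps**2 * k2)
        assert amp / a0 == pytest.approx(np.exp(-rate * t_end), rel=2e-3)

    def test_spatial_refinement_consistency(self, pf_params):
        # halving the spacing changes a smooth-field endpoint only slightly,
        # consistent with 2nd-order spatial accuracy
        def endpoint(n):
            grid = Grid(nx=n, ny=n, spacing=1160.0 / n)
            x = (np.arange(n) + 0.5) / n
            phi = 0.4 + 0.2 * np.cos(np.pi * x)[None, :] * np.cos(np.pi * x)[:, None]
            state = PhaseFieldState(phi, np.zeros((n, n)))
            traj = simulate_mobility_ch(pf_params, state, [0.0, 0.05], grid, dt=0.0025)
            return traj.states[-1].phi_T.mean(), traj.states[-1].phi_T.max()

        m32, mx32 = endpoint(32)
        m64, mx64 = endpoint(64)
        assert m32 == pytest.approx(m64, rel=1e-10)  # mass per area identical
        assert mx32 == pytest.approx(mx64, rel=0.05)


class TestFullPhaseField:
    def test_uniform_state_matches_reduced_system(self, grid32):
        p = ReducedParams(lambda_prol=0.5, lambda_apop=0.09, lambda_VN=0.11,
                          K=0.14, phi_sigma=0.5, phi_V0=0.0422)
        params = PhaseFieldParams(M_T=200.0, E_bar_T=0.65, epsilon_T=30.0, reduced=p)
        state = PhaseFieldState(np.full(grid32.shape, p.phi_V0), np.zeros(grid32.shape))
        times = np.linspace(0.0, 2.0, 5)
        traj = simulate_full_phase_field(params, state, 0.5, times, grid32,
                                         dt=0.01, ode_substeps=2)
        ode = simulate_necrosis_system(p, times, dt=0.005)
        for j, s in enumerate(traj.states):
            np.testing.assert_allclose(s.phi_T.mean(), ode.column("phi_T")[j], rtol=1e-6)
            np.testing.assert_allclose(s.phi_N.mean(), ode.column("phi_N")[j], rtol=1e-6)

    def test_rich_nutrient_keeps_necrosis_frozen(self, grid32):
        p = ReducedParams(lambda_prol=0.5, lambda_apop=0.09, lambda_VN=5.0,
                          K=0.14, phi_sigma=1.0, phi_V0=0.03, phi_N0=0.01)
        params = PhaseFieldParams(M_T=100.0, E_bar_T=0.65, epsilon_T=30.0, reduced=p)
        phi_n0 = np.full(grid32.shape, 0.01)
        state = PhaseFieldState(np.full(grid32.shape, 0.04), phi_n0)
        traj = simulate_full_phase_field(params, state, 1.0, [0.0, 0.5, 1.0], grid32,
                                         dt=0.01)
        for s in traj.states:
            np.testing.assert_array_equal(s.phi_N, phi_n0)

    def test_sourceless_run_reduces_to_mobility_model(self, grid32):
        rng = np.random.default_rng(3)
        phi = np.clip(0.4 + 0.1 * rng.standard_normal(grid32.shape), 0, 1)
        # smooth the noise so the CH step stays well inside [0, 1]
        from scipy.ndimage import gaussian_filter

        phi = gaussian_filter(phi, 2.0, mode="nearest")
        p = ReducedParams(lambda_prol=0.0, lambda_apop=0.0, lambda_VN=0.0,
                          K=0.14, phi_V0=0.01)
        params = PhaseFieldParams(M_T=200.0, E_bar_T=0.65, epsilon_T=30.0, reduced=p)
        state = PhaseFieldState(phi, np.zeros(grid32.shape))
        times = [0.0, 0.1, 0.2]
        full = simulate_full_phase_field(params, state, 0.5, times, grid32, dt=0.005)
        mob = simulate_mobility_ch(params, state, times, grid32, dt=0.005)
        np.testing.assert_allclose(full.states[-1].phi_T, mob.states[-1].phi_T,
                                   atol=1e-12)
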