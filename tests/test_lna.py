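import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import solve_lyapunov

import filaturing as ft
from filaturing.lna import _interior_peak

from conftest import equilibrium_counts


def site_space_noise_matrix(params, eq, lattice, volume=123.0):
    """Independent assembly of the 3Ω×3Ω noise covariance: outer products of
    channel stoichiometries weighted by equilibrium rates."""
    n = lattice.n_cells
    b = np.zeros((3 * n, 3 * n))
    for c in ft.build_channels(params, lattice, volume):
        rate = c.equilibrium_rate(eq.phi, eq.psi, eq.eta)
        vec = np.zeros(3 * n)
        for cell, species, delta in c.stoich:
            vec[species * n + cell] += delta
        b += rate * np.outer(vec, vec)
    return b


class TestMatrices:
    def test_drift_matches_jacobian(self, params_stable, eq_stable):
        mats = ft.lna_matrices(params_stable, eq_stable)
        j0, jd = ft.jacobian(params_stable, eq_stable)
        np.testing.assert_allclose(mats.m_ns, j0)
        np.testing.assert_allclose(mats.m_sp, jd)

    def test_decoupled_birth_death_noise(self):
        """Pure production/decay of HetR: B_11 = α_R + k_R φ* = 2 α_R."""
        p = ft.ModelParams(alpha_R=0.2, alpha_S=0, alpha_N=0, beta_R=0,
                           beta_S=0, k_R=0.2, k_S=1.0, k_N=1.0,
                           mu_S=0, mu_N=0, D_S=0, D_N=0)
        eq = ft.find_equilibrium(p)[0]
        mats = ft.lna_matrices(p, eq)
        assert mats.b_ns[0, 0] == pytest.approx(2 * p.alpha_R, abs=1e-12)

    @pytest.mark.parametrize("preset", ["fig3_red", "fig3_blue", "s2_blue"])
    def test_noise_matrix_matches_channel_outer_products(self, preset):
        """b_ns ⊗ I + hop part reproduces the channel-by-channel covariance."""
        import warnings

        p = ft.synthetic.preset(preset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eq = ft.reference_equilibrium(p)
            lat = ft.build_chain(4)
            mats = ft.lna_matrices(p, eq)
        n = 4
        expected = np.zeros((3 * n, 3 * n))
        for q in range(3):
            for l in range(3):
                block = mats.b_ns[q, l] * np.eye(n)
                if q == l:
                    # hop noise: −2 D c* Δ in site space
                    block += mats.b_sp[q, q] * lat.laplacian
                expected[q * n:(q + 1) * n, l * n:(l + 1) * n] = block
        assembled = site_space_noise_matrix(p, eq, lat)
        np.testing.assert_allclose(assembled, expected, atol=1e-12)

    def test_mode_space_noise_is_positive_semidefinite(
        self, params_stable, eq_stable, chain40
    ):
        mats = ft.lna_matrices(params_stable, eq_stable)
        for lam in chain40.eigenvalues:
            evals = np.linalg.eigvalsh(mats.noise(lam))
            assert evals.min() > -1e-12

    def test_unstable_equilibrium_warns(self):
        # this β_R sits in the window where the only root is unstable
        p = ft.synthetic.preset("s2_red").replace(beta_R=5.75)
        eqs = ft.find_equilibrium(p)
        unstable = [e for e in eqs if not e.stable_homogeneous]
        assert unstable
        with pytest.warns(UserWarning):
            ft.lna_matrices(p, unstable[0])


class TestTheoreticalSpectrum:
    def test_ou_lorentzian_closed_form(self):
        """Fully decoupled HetR: P(ω) = 2α_R / (ω² + k_R²) exactly."""
        p = ft.ModelParams(alpha_R=0.2, alpha_S=0.1, alpha_N=0.3, beta_R=0,
                           beta_S=0, k_R=0.2, k_S=0.1, k_N=0.7,
                           mu_S=0, mu_N=0, D_S=0, D_N=0)
        eq = ft.find_equilibrium(p)[0]
        omega = np.linspace(-3.0, 3.0, 121)
        spec = ft.theoretical_spectrum(p, eq, np.array([0.0]), omega)
        expected = 2 * p.alpha_R / (omega**2 + p.k_R**2)
        np.testing.assert_allclose(spec.power[0, :, 0], expected, atol=1e-10)

    def test_spectrum_is_even_in_frequency(self, params_stable, eq_stable):
        omega = np.linspace(-2.0, 2.0, 81)
        spec = ft.theoretical_spectrum(
            params_stable, eq_stable, np.array([0.0, -0.5]), omega
        )
        np.testing.assert_allclose(spec.power, spec.power[:, ::-1, :], atol=1e-12)
        assert np.all(spec.power >= 0)

    def test_spatial_slice_peaks_at_interior_mode(
        self, params_stable, eq_stable, chain40
    ):
        """Outside the deterministic region, P_1(0, Λ) still has a clear
        interior maximum — the stochastic Turing signature."""
        spec = ft.theoretical_spectrum(
            params_stable, eq_stable, chain40, omega_grid=np.array([0.0])
        )
        found, lam_star, height = _interior_peak(
            spec.power[0, 0], chain40.eigenvalues, min_ratio=1.2
        )
        assert found
        assert lam_star < -1e-3

    def test_noise_peak_matches_deterministic_wavelength(
        self, params_stable, eq_stable, params_unstable, eq_unstable, chain40
    ):
        """The stochastic peak mode coincides (within one discrete mode) with
        the mode that goes unstable just inside the deterministic region."""
        spec = ft.theoretical_spectrum(
            params_stable, eq_stable, chain40, omega_grid=np.array([0.0])
        )
        _, lam_star, _ = _interior_peak(
            spec.power[0, 0], chain40.eigenvalues, min_ratio=1.0
        )
        disp = ft.discrete_dispersion(params_unstable, eq_unstable, chain40)
        lams = chain40.eigenvalues  # descending
        i_spec = np.argmin(np.abs(lams - lam_star))
        i_det = np.argmin(np.abs(lams - disp.argmax_mode))
        assert abs(i_spec - i_det) <= 1

    def test_fluctuation_dissipation_consistency(self, params_stable, eq_stable):
        """∫ P(ω, Λ) dω / 2π equals the stationary Lyapunov variance."""
        mats = ft.lna_matrices(params_stable, eq_stable)
        for lam in (0.0, -1.0, -3.0):
            m = mats.drift(lam)
            b = mats.noise(lam)
            cov = solve_lyapunov(m, -b)
            eye = np.eye(3)
            for q in range(3):
                def integrand(om, q=q):
                    f = np.linalg.inv(-1j * om * eye - m)
                    return (f @ b @ f.conj().T)[q, q].real

                val, _ = quad(integrand, -np.inf, np.inf, limit=400)
                assert val / (2 * np.pi) == pytest.approx(
                    cov[q, q], rel=1e-6
                )


class TestEmpiricalSpectrum:
    def test_constant_trajectory_has_zero_spectrum(self, params_stable):
        lat = ft.build_chain(6)
        v = 100.0
        counts = np.full((6, 3), 50, dtype=np.int64)
        traj = ft.Trajectory(
            times=np.arange(0.0, 50.0, 1.0),
            fields=np.repeat(counts[None], 50, axis=0),
            mode="ssa",
            volume=v,
        )
        eq = ft.HomogeneousEquilibrium(0.5, 0.5, 0.5, 0.0, True)
        spec = ft.empirical_spectrum(traj, eq, lat, (0.0, 49.0))
        np.testing.assert_allclose(spec.power, 0.0, atol=1e-20)

    def test_window_outside_range_raises(self, params_stable, eq_stable):
        lat = ft.build_chain(3)
        init = equilibrium_counts(eq_stable, 50.0, 3)
        traj = ft.gillespie_run(params_stable, lat, 50.0, init, 10.0, seed=0)
        with pytest.raises(ValueError):
            ft.empirical_spectrum(traj, eq_stable, lat, (5.0, 20.0))

    def test_ensemble_statistics_match_linear_noise_theory(
        self, params_stable, eq_stable
    ):
        """Mode-resolved SSA variances agree with the Lyapunov solution, and
        the ensemble-averaged periodogram tracks the resolvent spectrum."""
        lat = ft.build_chain(3)
        volume = 2000.0
        init = equilibrium_counts(eq_stable, volume, 3)
        n_runs = 24
        mode_vars = []
        spectra = []
        for s in range(n_runs):
            traj = ft.gillespie_run(
                params_stable, lat, volume, init, 120.0, seed=500 + s, d_tau=0.5
            )
            conc = traj.fields / volume
            xi = np.sqrt(volume) * (conc - eq_stable.state)
            sel = traj.times >= 40.0
            coeffs = ft.mode_transform(xi[sel, :, 0], lat)
            mode_vars.append((coeffs**2).mean(axis=0))
            spec = ft.empirical_spectrum(traj, eq_stable, lat, (40.0, 120.0))
            spectra.append(spec.power)
        mode_vars = np.array(mode_vars)
        mats = ft.lna_matrices(params_stable, eq_stable)
        for j, lam in enumerate(lat.eigenvalues):
            cov = solve_lyapunov(mats.drift(lam), -mats.noise(lam))
            se = mode_vars[:, j].std(ddof=1) / np.sqrt(n_runs)
            assert abs(mode_vars[:, j].mean() - cov[0, 0]) < 3 * se

        mean_spec = np.mean(spectra, axis=0)
        se_spec = np.std(spectra, axis=0, ddof=1) / np.sqrt(n_runs)
        theory = ft.theoretical_spectrum(
            params_stable, eq_stable, lat, omega_grid=spec.omega
        )
        # compare away from ω = 0 (finite-window bias dominates the lowest bin)
        mask = (spec.omega > 0.1) & (spec.omega < 1.5)
        for j in range(3):
            diff = np.abs(mean_spec[0, mask, j] - theory.power[0, mask, j])
            assert np.mean(diff < 4 * se_spec[0, mask, j]) > 0.9
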