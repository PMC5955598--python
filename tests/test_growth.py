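import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import filaturing as ft

from conftest import equilibrium_counts


def chemistry_off():
    return ft.ModelParams(
        alpha_R=0, alpha_S=0, alpha_N=0, beta_R=0, beta_S=0,
        k_R=0, k_S=0, k_N=0, mu_S=0, mu_N=0, D_S=0, D_N=0,
    )


class TestGrowthConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ft.GrowthConfig(rho=-1.0)
        with pytest.raises(ValueError):
            ft.GrowthConfig(n_cells_init=1)
        with pytest.raises(ValueError):
            ft.GrowthConfig(splitting="thirds")


class TestStochasticGrowth:
    def test_zero_rate_identical_to_fixed_chain_run(
        self, params_stable, eq_stable
    ):
        """ρ = 0 reproduces the fixed-filament SSA exactly, seed for seed."""
        lat = ft.build_chain(6)
        volume = 80.0
        init = equilibrium_counts(eq_stable, volume, 6)
        fixed = ft.gillespie_run(params_stable, lat, volume, init, 20.0, seed=5)
        cfg = ft.GrowthConfig(rho=0.0, n_cells_init=6, max_cells=6)
        grown = ft.ssa_growing_run(params_stable, volume, cfg, init, 20.0, seed=5)
        np.testing.assert_array_equal(fixed.fields, grown.fields[:, :6, :])
        assert np.all(grown.n_cells == 6)

    def test_mean_cell_count_follows_exponential_law(self):
        """Chemistry off: Ω(τ) is a Yule process, E[Ω] = Ω₀ e^{ρVτ}."""
        cfg = ft.GrowthConfig(rho=2e-4, n_cells_init=4, max_cells=256)
        volume = 100.0
        init = np.full((4, 3), 10, dtype=np.int64)
        counts = []
        for seed in range(200):
            traj = ft.ssa_growing_run(
                chemistry_off(), volume, cfg, init, 60.0, seed=seed, d_tau=10.0
            )
            counts.append(traj.n_cells)
        counts = np.array(counts, dtype=float)
        t = np.arange(0.0, 61.0, 10.0)
        expected = 4 * np.exp(cfg.rho * volume * t)
        se = counts.std(axis=0, ddof=1) / np.sqrt(200)
        dev = np.abs(counts.mean(axis=0) - expected)
        assert np.all(dev[1:] < 3 * se[1:])
        # Yule variance: Ω₀ e^{ρVτ}(e^{ρVτ} − 1)
        g = np.exp(cfg.rho * volume * t[-1])
        var_expected = 4 * g * (g - 1)
        assert counts[:, -1].var(ddof=1) == pytest.approx(var_expected, rel=0.5)

    def test_equal_split_conserves_molecules(self):
        cfg = ft.GrowthConfig(rho=5e-3, n_cells_init=4, max_cells=64)
        init = np.array([[11, 7, 4]] * 4, dtype=np.int64)
        traj = ft.ssa_growing_run(
            chemistry_off(), 100.0, cfg, init, 15.0, seed=3, d_tau=3.0
        )
        totals = traj.fields.sum(axis=1)
        assert np.all(totals == totals[0])
        assert traj.n_cells[-1] > 4
        assert any(e[0] == "division" for e in traj.events)

    def test_binomial_split_preserves_totals_too(self):
        """Binomial allocation moves molecules between daughters but never
        creates or destroys them."""
        cfg = ft.GrowthConfig(
            rho=5e-3, n_cells_init=4, max_cells=64, splitting="binomial"
        )
        init = np.array([[11, 7, 4]] * 4, dtype=np.int64)
        traj = ft.ssa_growing_run(
            chemistry_off(), 100.0, cfg, init, 15.0, seed=3, d_tau=3.0
        )
        totals = traj.fields.sum(axis=1)
        assert np.all(totals == totals[0])

    def test_cap_truncates_cleanly(self):
        cfg = ft.GrowthConfig(rho=5e-2, n_cells_init=4, max_cells=8)
        init = np.full((4, 3), 5, dtype=np.int64)
        traj = ft.ssa_growing_run(
            chemistry_off(), 100.0, cfg, init, 30.0, seed=1, d_tau=10.0
        )
        assert traj.n_cells.max() == 8
        assert any(e[0] == "truncated" for e in traj.events)

    def test_split_rules_give_equivalent_pattern_spacings(self, params_unstable):
        """Equal and binomial division produce statistically indistinguishable
        inter-peak spacing distributions (two-sample test, α = 0.01)."""
        eq = ft.reference_equilibrium(params_unstable)
        volume = 200.0
        omega0 = 20
        rho = 2e-3 / volume  # grows ~20 → ~35 cells over τ = 300
        init = equilibrium_counts(eq, volume, omega0)
        spacings = {}
        for rule in ("equal", "binomial"):
            cfg = ft.GrowthConfig(
                rho=rho, n_cells_init=omega0, max_cells=128, splitting=rule
            )
            vals = []
            for seed in (11, 12, 13, 14):
                traj = ft.ssa_growing_run(
                    params_unstable, volume, cfg, init, 300.0, seed=seed, d_tau=50.0
                )
                omega_end = int(traj.n_cells[-1])
                smooth = np.convolve(
                    traj.fields[-1, :omega_end, 0], np.ones(3) / 3, mode="same"
                )
                m = ft.pattern_metrics(smooth, prominence=0.3 * smooth.std())
                vals.extend(m["spacings"])
            spacings[rule] = np.array(vals)
        assert spacings["equal"].size >= 4
        assert spacings["binomial"].size >= 4
        _, pval = mannwhitneyu(spacings["equal"], spacings["binomial"])
        assert pval > 0.01


class TestContinuumGrowth:
    def test_pure_dilution_closed_form(self):
        """Chemistry off, ρ̃ > 0, uniform start: c(τ) = c₀ e^{−ρ̃τ}."""
        rho_t = 0.01
        init = np.full((21, 3), 2.0)
        traj = ft.integrate_growing_continuum(
            chemistry_off(), rho_t, init, 100.0, n_samples=11
        )
        expected = 2.0 * np.exp(-rho_t * traj.times)
        np.testing.assert_allclose(
            traj.fields[:, 10, :], np.tile(expected[:, None], (1, 3)), rtol=1e-6
        )

    def test_zero_growth_reduces_to_fixed_domain_dynamics(
        self, params_stable, eq_stable
    ):
        init = np.tile(eq_stable.state, (31, 1))
        traj = ft.integrate_growing_continuum(
            params_stable, 0.0, init, 50.0, n_samples=6
        )
        drift = np.max(np.abs(traj.fields - init[None]))
        assert drift < 1e-6

    def test_dilution_never_drives_concentrations_negative(self, params_stable):
        init = np.tile([0.01, 0.01, 0.01], (21, 1))
        traj = ft.integrate_growing_continuum(
            params_stable, 0.05, init, 200.0, n_samples=21
        )
        assert traj.fields.min() >= 0.0

    def test_growth_preserves_characteristic_spacing(
        self, params_unstable, eq_unstable
    ):
        """Peaks are inserted as the domain grows; the spacing in cell units
        stays near the fixed-domain wavelength."""
        profile = ft.synthetic.gen_perturbed_field(eq_unstable, 1e-3, 161, seed=0)
        traj = ft.integrate_growing_continuum(
            params_unstable, 5e-5, profile, 14000.0,
            n_cells_init=40, n_samples=57,
        )
        m = ft.pattern_metrics(traj.fields[-1, :, 0])
        spacing_cells = np.diff(m["peaks"]) / 160.0 * traj.n_cells[-1]
        cd = ft.continuum_dispersion(params_unstable, eq_unstable)
        target = 2 * np.pi / cd.argmax_mode
        assert m["peaks"].size >= 5  # new peaks inserted (40-cell start fits ~3)
        assert abs(np.median(spacing_cells) - target) <= 2.0


class TestUnstableBand:
    def test_band_widens_and_leading_mode_linear_in_length(self, params_unstable):
        omegas = np.arange(10, 81, 5)
        table = ft.unstable_band(params_unstable, omegas)
        n_unstable = table["n_unstable"].to_numpy()
        assert np.all(np.diff(n_unstable) >= 0)
        fit_sel = table["omega"] >= 20
        x = table.loc[fit_sel, "omega"].to_numpy(dtype=float)
        y = table.loc[fit_sel, "leading_mode"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        r2 = 1 - np.sum((y - slope * x - intercept) ** 2) / np.sum(
            (y - y.mean()) ** 2
        )
        assert r2 > 0.99
        assert slope > 0

    def test_two_cell_filament_has_at_most_one_nonuniform_mode(
        self, params_unstable
    ):
        table = ft.unstable_band(params_unstable, [2])
        assert table["n_unstable"].iloc[0] <= 1

    def test_stable_parameters_yield_empty_band(self, params_stable):
        table = ft.unstable_band(params_stable, [20, 40])
        assert (table["n_unstable"] == 0).all()
        assert table["leading_mode"].isna().all()
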