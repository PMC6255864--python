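"""2D dissociation constants, equilibrium distributions and energetics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hsafm as H


def binding_fraction(a, kd):
    return a / (a + kd)


class TestKdFit:
    def test_midpoint_and_noiseless_exact(self):
        """At [A] = Kd the bound fraction is 1/2; noiseless data generated
        at Kd = 220 µm⁻² refits to 220 to machine precision."""
        kd = 220.0
        a = np.array([kd / 3, kd, 3 * kd])
        f = binding_fraction(a, kd)
        assert f[1] == pytest.approx(0.5)
        fit = H.fit_kd_curve(a, f)
        assert fit.kd == pytest.approx(kd, rel=1e-9)

    def test_noisy_replicates_within_ten_percent(self):
        """5% multiplicative noise, 8 points spanning 0.1-10x Kd: the
        median recovered Kd over 100 replicates is within 10%."""
        kd = 220.0
        rng = np.random.default_rng(42)
        a = np.logspace(np.log10(0.1 * kd), np.log10(10 * kd), 8)
        est = []
        for _ in range(100):
            f = np.clip(binding_fraction(a, kd) * rng.normal(1, 0.05, 8), 0, 1)
            est.append(H.fit_kd_curve(a, f).kd)
        assert abs(np.median(est) - kd) / kd < 0.10

    def test_confidence_interval_brackets_truth(self):
        rng = np.random.default_rng(1)
        a = np.logspace(1, 3.5, 10)
        f = np.clip(binding_fraction(a, 220.0) + rng.normal(0, 0.01, 10), 0, 1)
        fit = H.fit_kd_curve(a, f)
        assert fit.ci95[0] < 220.0 < fit.ci95[1]

    def test_degenerate_titrations_rejected(self):
        with pytest.raises(ValueError):
            H.fit_kd_curve([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            H.fit_kd_curve([1.0, 2.0], [0.2, 0.4])
        with pytest.raises(ValueError):
            H.fit_kd_curve([1.0, 2.0, 3.0], [0.1, 1.2, 0.3])


class TestKdMatrix:
    def test_published_matrix_layout(self):
        kds = H.annexin_kd_matrix()
        assert kds.monomer_row.tolist() == [220.0, 170.0, 650.0, 200.0]
        flags = kds.reduced_reliability()
        assert not flags.loc["monomer", "tetramer"]  # 5 units: still reliable
        assert flags.loc["dimer", "tetramer"]        # 6 units: pooled in fits
        assert flags.loc["tetramer", "tetramer"]

    def test_csv_round_trip(self, tmp_path):
        kds = H.annexin_kd_matrix()
        p = tmp_path / "kd.csv"
        kds.to_csv(p)
        back = H.KdMatrix.from_csv(p)
        assert np.allclose(back.values.to_numpy(), kds.values.to_numpy())

    def test_positive_entries_required(self):
        import pandas as pd
        with pytest.raises(ValueError):
            H.KdMatrix(values=pd.DataFrame([[1.0, -2.0], [3.0, 4.0]]))


class TestEquilibriumDistribution:
    def test_dilute_limit_is_all_monomer(self):
        state = H.equilibrium_distribution(1e-6, [220.0])
        f = state.mass_fractions
        assert f[0] > 0.999
        assert np.all(f[1:] < 1e-3)

    def test_two_species_closed_form(self):
        """Monomer/dimer only: the free monomer solves the quadratic
        2 a²/K + a = c_total; the solver matches it to 1e-12 relative."""
        K, c = 150.0, 800.0
        state = H.equilibrium_distribution(c, [K], n_max=2)
        a_closed = (-K + np.sqrt(K ** 2 + 8 * K * c)) / 4
        assert state.densities[0] == pytest.approx(a_closed, rel=1e-12)
        assert state.densities[1] == pytest.approx(a_closed ** 2 / K, rel=1e-12)

    @given(c=st.floats(1e-3, 1e5),
           kds=st.lists(st.floats(1.0, 5e3), min_size=1, max_size=4))
    @settings(max_examples=200, deadline=None)
    def test_mass_conservation(self, c, kds):
        state = H.equilibrium_distribution(c, np.array(kds))
        total = (np.arange(1, state.n_max + 1) * state.densities).sum()
        assert abs(total - c) / c < 1e-9
        assert np.all(state.densities >= 0)
        assert state.mass_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_monomer_fraction_decreases_with_total(self):
        kds = H.annexin_kd_matrix()
        grid = np.logspace(0, 4, 60)
        f1 = [H.equilibrium_distribution(c, kds).mass_fractions[0] for c in grid]
        assert np.all(np.diff(f1) < 0)

    def test_oligomer_fractions_unimodal_with_increasing_peaks(self):
        """Dimer, trimer, tetramer mass fractions are unimodal in c_total
        and attain their maxima at strictly increasing concentrations."""
        kds = H.annexin_kd_matrix()
        grid = np.logspace(0, 4, 400)
        sweep = H.equilibrium_sweep(grid, kds)
        argmaxes = []
        for col in ["f2", "f3", "f4"]:
            y = sweep[col].to_numpy()
            i = int(np.argmax(y))
            rising, falling = np.diff(y[:i + 1]), np.diff(y[i:])
            assert np.all(rising > -1e-12) and np.all(falling < 1e-12)
            argmaxes.append(grid[i])
        assert argmaxes[0] < argmaxes[1] < argmaxes[2]

    def test_dimer_peak_near_dimer_kd(self):
        """The dimer mass fraction peaks at a total concentration near the
        monomer-monomer Kd of 220 µm⁻² (dense-grid argmax oracle)."""
        kds = H.annexin_kd_matrix()
        grid = np.logspace(0, 4, 2000)
        f2 = np.array([H.equilibrium_distribution(c, kds).mass_fractions[1]
                       for c in grid])
        c_peak = grid[int(np.argmax(f2))]
        assert 110.0 <= c_peak <= 440.0  # within a factor 2 of 220

    def test_zero_total_concentration(self):
        state = H.equilibrium_distribution(0.0, [220.0])
        assert np.all(state.densities == 0)
        assert state.mass_fractions[0] == 1.0


class TestFreeEnergies:
    def test_oligomer_free_energy_basics(self):
        assert H.oligomer_free_energy(5.0, 5.0) == 0.0
        assert H.oligomer_free_energy(5 * np.e, 5.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            H.oligomer_free_energy(0.0, 5.0)

    def test_free_energy_consistent_with_equilibrium_state(self):
        state = H.equilibrium_distribution(500.0, H.annexin_kd_matrix())
        d = state.densities
        for n, m in [(2, 1), (3, 1), (4, 2)]:
            dg = H.oligomer_free_energy(d[n - 1], d[m - 1])
            assert dg == pytest.approx(np.log(d[n - 1] / d[m - 1]), rel=1e-12)

    def test_partition_coefficient_basics(self):
        from hsafm.units import molar_to_per_um3
        # P = 1 when the volumized surface density equals the bulk density
        c_bulk = 1e-7
        c_surface = molar_to_per_um3(c_bulk) * 2e-3
        be = H.membrane_binding_free_energy(c_surface, c_bulk, slab_thickness=2.0)
        assert be.delta_g0 == pytest.approx(0.0, abs=1e-12)
        be2 = H.membrane_binding_free_energy(c_surface * np.e, c_bulk, 2.0)
        assert be2.delta_g0 == pytest.approx(-1.0, rel=1e-12)

    def test_dilute_binding_free_energy_scale(self):
        """127 nM bulk against 1.0 µm⁻² surface under a 2 nm slab gives
        ΔG0 ≈ -1.9 kBT (close to the measured -1.7 kBT at low calcium)."""
        be = H.membrane_binding_free_energy(1.0, 127e-9, 2.0)
        assert be.delta_g0 == pytest.approx(-1.88, abs=0.02)

    def test_invalid_slab(self):
        with pytest.raises(ValueError):
            H.membrane_binding_free_energy(1.0, 1e-7, 0.0)


class TestSaffmanDelbruck:
    def test_exact_data_recovered(self):
        r = np.array([4.15, 5.9, 7.2, 8.3, 9.3])
        a, b = 0.35, 60.0
        d = a * np.log(b / r)
        fit = H.fit_saffman_delbruck(r, d)
        assert fit.amplitude == pytest.approx(a, rel=1e-9)
        assert fit.length == pytest.approx(b, rel=1e-6)

    def test_published_diffusion_series(self):
        """The measured oligomer series D = 0.8..0.46 µm²/s at radii
        r1*sqrt(n) fits the log model with small residuals and a strictly
        decreasing fitted curve."""
        r1 = 8.3 / 2
        n = np.arange(1, 6)
        r = r1 * np.sqrt(n)
        d = np.array([0.8, 0.63, 0.58, 0.50, 0.46])
        fit = H.fit_saffman_delbruck(r, d)
        assert fit.residual_rms < 0.05
        assert np.all(np.diff(fit.d_fitted) < 0)
        assert fit.length > r.max()

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            H.fit_saffman_delbruck([4.0, 6.0], [0.8, 0.6])

    def test_increasing_series_warns(self):
        with pytest.warns(UserWarning):
            H.fit_saffman_delbruck([4.0, 6.0, 8.0], [0.5, 0.6, 0.7])


class TestCriticalCalcium:
    def test_exact_exponential_recovered(self):
        ca = np.array([50.0, 100.0, 150.0, 200.0])
        c = 0.2 * np.exp(0.035 * ca)
        fit = H.fit_critical_calcium(ca, c, c_critical=500.0)
        assert fit.amplitude == pytest.approx(0.2, rel=1e-9)
        assert fit.rate == pytest.approx(0.035, rel=1e-9)
        assert fit.ca_at_critical == pytest.approx(np.log(500 / 0.2) / 0.035,
                                                   rel=1e-9)

    def test_two_printed_anchors_give_order_of_measured_crossing(self):
        """Solving the exponential through (50 µM, 1.0 µm⁻²) and
        (200 µM, 285 µm⁻²) puts the 500 µm⁻² critical coverage near
        215 µM -- the same order as the measured 240 ± 10 µM."""
        fit = H.fit_critical_calcium([50.0, 200.0], [1.0, 285.0], 500.0)
        assert fit.ca_at_critical == pytest.approx(215.0, abs=1.0)

    def test_noisy_recovery_median_within_ten_percent(self):
        rng = np.random.default_rng(3)
        ca = np.linspace(40, 240, 6)
        truth = H.fit_critical_calcium(ca, 0.15 * np.exp(0.04 * ca), 500.0)
        est = []
        for _ in range(100):
            c = 0.15 * np.exp(0.04 * ca) * rng.normal(1, 0.10, 6)
            est.append(H.fit_critical_calcium(ca, c, 500.0).ca_at_critical)
        assert abs(np.median(est) - truth.ca_at_critical) / truth.ca_at_critical < 0.10

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            H.fit_critical_calcium([50.0, 100.0], [0.0, 10.0], 500.0)
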