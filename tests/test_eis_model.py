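"""Forward EIS model: oracles, passivity, features, monotonicities."""

import numpy as np
import pytest

import defect2eis as d2e
from defect2eis.eis_model import NM_TO_CM, UF_TO_F, FEMSystem
from defect2eis.exceptions import GeometryError, NoInteriorMinimumError, ParameterError


def radial_fd_spectrum(mp, domain_radius_nm, fg, n_nodes=10_000):
    """Independent 1D finite-difference solve of the radial thin-film problem."""
    r = np.linspace(mp.r_def, domain_radius_nm, n_nodes) * NM_TO_CM
    h = r[1] - r[0]
    g_s = mp.g_s
    c_tot = mp.c_total_f
    c_m = mp.c_m * UF_TO_F
    c_h = mp.c_h * UF_TO_F
    out = np.empty(len(fg), complex)
    for i, f in enumerate(fg.array):
        w = 2 * np.pi * f
        n = len(r)
        main = np.full(n, -2.0 * g_s / h**2 - 1j * w * c_tot, complex)
        upper = g_s / h**2 + g_s / (2 * h * r[:-1])
        lower = g_s / h**2 - g_s / (2 * h * r[1:])
        rhs = np.full(n, -1j * w * c_m * mp.u0, complex)
        # u(r_def) = U0; u'(R) = 0 via ghost-node reflection
        main[0], upper[0], rhs[0] = 1.0, 0.0, mp.u0
        main[-1] = -2.0 * g_s / h**2 - 1j * w * c_tot
        lower[-1] = 2.0 * g_s / h**2
        from scipy.sparse import diags
        from scipy.sparse.linalg import spsolve

        a = diags([lower, main, upper], [-1, 0, 1], format="csc")
        u = spsolve(a, rhs)
        integral = np.trapezoid(u * r, r)
        rd_cm, big_r_cm = mp.r_def * NM_TO_CM, domain_radius_nm * NM_TO_CM
        out[i] = (
            1j * w * c_h * (2 * np.pi * integral + mp.u0 * np.pi * rd_cm**2)
            / (np.pi * big_r_cm**2 * mp.u0)
        )
    return d2e.EISSpectrum(fg.array.copy(), out)


class TestZeroDefectLimit:
    def test_series_capacitor_solution(self):
        empty = d2e.DefectSet((), 4000, 4000)
        mp = d2e.MembraneParams()
        fg = d2e.FrequencyGrid.logspaced(0.1, 1e5, 5)
        sp = d2e.model_spectrum(empty, mp, fg)
        c_s = mp.c_series * UF_TO_F
        np.testing.assert_allclose(sp.admittance.imag, 2 * np.pi * fg.array * c_s, rtol=1e-12)
        np.testing.assert_allclose(sp.phase_deg, 90.0, atol=1e-9)

    def test_flat_phase_has_no_interior_minimum(self):
        empty = d2e.DefectSet((), 4000, 4000)
        sp = d2e.model_spectrum(empty, d2e.MembraneParams(), d2e.FrequencyGrid.logspaced(1, 1e4, 4))
        with pytest.raises(NoInteriorMinimumError):
            d2e.spectral_features(sp)


class TestRadialOracle:
    def test_defect_filling_domain_gives_helmholtz_capacitance(self):
        mp = d2e.MembraneParams(r_def=999.0)
        fg = d2e.FrequencyGrid.logspaced(1, 100, 3)
        sp = d2e.radial_spectrum(mp, 1000.0, fg)
        c_h = mp.c_h * UF_TO_F
        np.testing.assert_allclose(
            sp.admittance.imag, 2 * np.pi * fg.array * c_h, rtol=2e-2
        )

    def test_low_frequency_blocking_limit(self):
        mp = d2e.MembraneParams(r_def=5.0)
        fg = d2e.FrequencyGrid((1e-5, 2e-5, 4e-5))
        sp = d2e.radial_spectrum(mp, 500.0, fg)
        assert np.all(sp.phase_deg > 89.9)

    def test_matches_finite_difference_solver(self):
        mp = d2e.MembraneParams(r_def=5.0, rho_sub=10**4.5)
        fg = d2e.FrequencyGrid(tuple(np.logspace(0, 4, 9)))
        bessel = d2e.radial_spectrum(mp, 1000.0, fg)
        fd = radial_fd_spectrum(mp, 1000.0, fg)
        assert np.abs(bessel.phase_deg - fd.phase_deg).max() < 0.1

    def test_high_kr_asymptotic_regime_is_finite(self):
        # far into the overflow regime of I_v(kR)
        mp = d2e.MembraneParams(r_def=2.0, rho_sub=1e6)
        fg = d2e.FrequencyGrid((1e5, 2e5, 4e5))
        sp = d2e.radial_spectrum(mp, 2000.0, fg)
        assert np.all(np.isfinite(sp.admittance))
        assert np.all((sp.phase_deg >= 0) & (sp.phase_deg <= 90))


class TestFEMOracleEquivalence:
    def test_single_centered_defect_disk_domain(self):
        """2D FEM and the radial Bessel solution agree to <1% |Y|, <0.5 deg."""
        mp = d2e.MembraneParams(r_def=5.0, rho_sub=10**4.5)
        fg = d2e.FrequencyGrid.logspaced(0.1, 1e5, 4)
        ds = d2e.DefectSet.from_coordinates([[1000.0, 1000.0]], 2000, 2000)
        system = FEMSystem(
            ds, mp.r_def, d2e.MeshParams(h_far=100.0), domain="disk", domain_radius=1000.0
        )
        fem = system.solve(mp, fg)
        bessel = d2e.radial_spectrum(mp, 1000.0, fg)
        rel = np.abs(fem.admittance - bessel.admittance) / np.abs(bessel.admittance)
        assert rel.max() < 0.01
        assert np.abs(fem.phase_deg - bessel.phase_deg).max() < 0.5


class TestFEMProperties:
    def test_admittance_independent_of_drive_amplitude(self, small_defect_set, fast_mesh, fast_grid):
        sp1 = d2e.model_spectrum(
            small_defect_set, d2e.MembraneParams(r_def=3.0, u0=1.0), fast_grid, fast_mesh
        )
        sp2 = d2e.model_spectrum(
            small_defect_set, d2e.MembraneParams(r_def=3.0, u0=7.5), fast_grid, fast_mesh
        )
        np.testing.assert_allclose(sp1.admittance, sp2.admittance, rtol=1e-10)

    def test_passivity(self, small_defect_set, fast_mesh, fast_grid):
        for rho_exp, r in ((4.0, 1.0), (4.5, 5.0), (5.0, 13.0)):
            sp = d2e.model_spectrum(
                small_defect_set,
                d2e.MembraneParams(r_def=r, rho_sub=10**rho_exp),
                fast_grid,
                fast_mesh,
            )
            assert np.all(sp.admittance.real >= -1e-15)
            assert np.all((sp.phase_deg >= 0.0) & (sp.phase_deg <= 90.0 + 1e-9))

    def test_phase_rises_to_90_above_minimum(self, small_defect_set, fast_mesh):
        fg = d2e.FrequencyGrid.logspaced(0.1, 1e5, 4)
        sp = d2e.model_spectrum(
            small_defect_set, d2e.MembraneParams(r_def=3.0), fg, fast_mesh
        )
        phase = sp.phase_deg
        idx = int(np.argmin(phase))
        assert np.all(np.diff(phase[idx:]) > 0)
        assert phase[-1] > 85.0

    def test_fmin_decreases_with_rho_sub(self, small_defect_set, fast_mesh, fast_grid):
        f_mins = []
        system = FEMSystem(small_defect_set, 3.0, fast_mesh)
        for rho_exp in (4.0, 4.5, 5.0):
            sp = system.solve(d2e.MembraneParams(r_def=3.0, rho_sub=10**rho_exp), fast_grid)
            f_mins.append(d2e.spectral_features(sp).f_min)
        assert f_mins[0] > f_mins[1] > f_mins[2]

    def test_fmin_increases_with_density(self, fast_mesh, fast_grid):
        from conftest import sample_separated

        rng = np.random.default_rng(2)
        mp = d2e.MembraneParams(r_def=3.0)
        xy_low = sample_separated(rng, 10, 30, 1470, 30)
        xy_high = np.vstack([xy_low, sample_separated(rng, 10, 30, 1470, 30)])
        f = []
        for xy in (xy_low, xy_high):
            ds = d2e.DefectSet.from_coordinates(xy, 1500, 1500)
            sp = d2e.model_spectrum(ds, mp, fast_grid, fast_mesh)
            f.append(d2e.spectral_features(sp).f_min)
        assert f[1] > f[0]

    def test_density_doubling_shifts_fmin_by_log2(self, fast_mesh):
        """Dilute regime: doubling defect density doubles f_min (~ -0.30 decades)."""
        from conftest import sample_separated

        fg = d2e.FrequencyGrid.logspaced(0.1, 1e4, 5)
        mp = d2e.MembraneParams(r_def=2.0, rho_sub=10**4.5)
        deltas = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = sample_separated(rng, 12, 30, 1970, 40)
            b = sample_separated(rng, 12, 30, 1970, 40)
            true = d2e.DefectSet.from_coordinates(a, 2000, 2000)
            pred = d2e.DefectSet.from_coordinates(np.vstack([a, b]), 2000, 2000)
            sp_t = d2e.model_spectrum(true, mp, fg, fast_mesh)
            sp_p = d2e.model_spectrum(pred, mp, fg, fast_mesh)
            deltas.append(d2e.compare_spectra(sp_t, sp_p).delta_f_log)
        assert np.mean(deltas) == pytest.approx(-np.log10(2.0), abs=0.05)

    def test_clustering_changes_spectral_features(self, fast_mesh, fast_grid):
        # same N and field: strongly clustered vs homogeneous patterns differ
        from conftest import sample_separated

        rng = np.random.default_rng(5)
        homogeneous = sample_separated(rng, 24, 40, 1960, 60)
        centers = np.array([[500.0, 500.0], [1500.0, 1400.0], [700.0, 1600.0]])
        clustered = []
        for c in centers:
            for k in range(8):
                ang = 2 * np.pi * k / 8 + rng.uniform(0, 0.3)
                rad = 60.0 + 45.0 * (k % 3)
                clustered.append(c + rad * np.array([np.cos(ang), np.sin(ang)]))
        clustered = np.array(clustered)
        mp = d2e.MembraneParams(r_def=3.0)
        feats = []
        for xy in (homogeneous, clustered):
            ds = d2e.DefectSet.from_coordinates(xy, 2000, 2000)
            sp = d2e.model_spectrum(ds, mp, fast_grid, fast_mesh)
            feats.append(d2e.spectral_features(sp))
        assert abs(np.log10(feats[0].f_min / feats[1].f_min)) > 0.02

    def test_overlapping_disks_rejected(self):
        ds = d2e.DefectSet.from_coordinates([[100.0, 100.0], [104.0, 100.0]], 1000, 1000)
        with pytest.raises(GeometryError):
            d2e.model_spectrum(ds, d2e.MembraneParams(r_def=5.0), d2e.FrequencyGrid.logspaced(1, 100, 3))


class TestSpectralFeatures:
    def test_synthetic_parabola_recovered_exactly(self):
        fg = d2e.FrequencyGrid.logspaced(0.1, 1e5, 10)
        logf = np.log10(fg.array)
        phase = 40.0 + (logf - 1.3) ** 2
        admittance = 1e-6 * np.exp(1j * np.radians(phase))
        feat = d2e.spectral_features(d2e.EISSpectrum(fg.array, admittance))
        assert np.log10(feat.f_min) == pytest.approx(1.3, abs=1e-9)
        assert feat.arg_y_min == pytest.approx(40.0, abs=1e-9)

    def test_refinement_stable_under_grid_doubling(self):
        mp = d2e.MembraneParams(r_def=5.0)
        coarse = d2e.radial_spectrum(mp, 178.0, d2e.FrequencyGrid.logspaced(0.1, 1e5, 10))
        fine = d2e.radial_spectrum(mp, 178.0, d2e.FrequencyGrid.logspaced(0.1, 1e5, 20))
        fc = d2e.spectral_features(coarse)
        ff = d2e.spectral_features(fine)
        assert abs(np.log10(fc.f_min) - np.log10(ff.f_min)) < 0.01

    def test_compare_identity_and_antisymmetry(self):
        mp = d2e.MembraneParams(r_def=5.0)
        fg = d2e.FrequencyGrid.logspaced(0.1, 1e5, 10)
        a = d2e.radial_spectrum(mp, 178.0, fg)
        b = d2e.radial_spectrum(d2e.MembraneParams(r_def=5.0, rho_sub=10**4.2), 178.0, fg)
        same = d2e.compare_spectra(a, a)
        assert (same.delta_f_log, same.delta_arg_y) == (0.0, 0.0)
        fwd = d2e.compare_spectra(a, b)
        rev = d2e.compare_spectra(b, a)
        assert fwd.delta_f_log == pytest.approx(-rev.delta_f_log)
        assert fwd.delta_arg_y == pytest.approx(-rev.delta_arg_y)


class TestSpectrumIO:
    def test_csv_round_trip(self, tmp_path):
        mp = d2e.MembraneParams(r_def=5.0)
        sp = d2e.radial_spectrum(mp, 500.0, d2e.FrequencyGrid.logspaced(1, 1e4, 4))
        path = tmp_path / "spectrum.csv"
        sp.write_csv(path)
        back = d2e.EISSpectrum.read_csv(path)
        np.testing.assert_allclose(back.admittance, sp.admittance, rtol=1e-9)

    def test_invalid_frequency_grid_rejected(self):
        with pytest.raises(ParameterError):
            d2e.FrequencyGrid((10.0, 5.0, 1.0))
        with pytest.raises(ParameterError):
            d2e.FrequencyGrid((-1.0, 5.0, 10.0))
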