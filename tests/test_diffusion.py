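"""Lateral MSD, round-trip-time D_zz inversion, region labels, ratios."""
import numpy as np
import pandas as pd
import pytest

import tetherlytics as tl
from tetherlytics.constants import beta
from tetherlytics.data import lateral_diffusion_table
from tetherlytics.diffusion import DiffusionError, _msd_fft


@pytest.fixture(scope="module")
def narrow_slab():
    return tl.SlabDomain(z_b=0.0, z_t=2.0, L_x=10.0, L_y=10.0)


@pytest.fixture(scope="module")
def narrow_flat_traj(narrow_slab):
    """Flat F, D = 1: round trips complete many times per trajectory."""
    spec = tl.LangevinSpec(domain=narrow_slab, diffusion_z=1.0, n_particles=10,
                           dt=1e-3, n_steps=100_000, seed=3)
    return tl.simulate_overdamped(spec)


@pytest.fixture(scope="module")
def linear_F_traj(narrow_slab):
    """Linear tilt F = a z, Boltzmann-initialized."""
    a = 1.5  # kJ/mol/nm
    spec = tl.LangevinSpec(domain=narrow_slab,
                           free_energy=lambda z: a * np.asarray(z),
                           diffusion_z=1.0, temperature=320.0, n_particles=10,
                           dt=1e-3, n_steps=100_000, seed=4, init="boltzmann")
    return tl.simulate_overdamped(spec), a


def synthetic_xy_traj(Dx, Dy, n_particles=50, n_frames=2000, dt=0.01, seed=0):
    """Pure lateral Gaussian increments with per-axis diffusivities."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, 1, size=(n_frames - 1, n_particles, 2))
    steps[:, :, 0] *= np.sqrt(2 * Dx * dt)
    steps[:, :, 1] *= np.sqrt(2 * Dy * dt)
    pos = np.zeros((n_frames, n_particles, 3))
    pos[1:, :, :2] = np.cumsum(steps, axis=0)
    pos[..., 2] = 1.0
    dom = tl.SlabDomain(z_b=0.0, z_t=2.0, L_x=1e6, L_y=1e6)
    return tl.Trajectory(times=dt * np.arange(n_frames), positions=pos,
                         species=np.full(n_particles, "W"), domain=dom)


class TestLateralMSD:
    def test_stationary_particles_zero_diffusion(self):
        traj = synthetic_xy_traj(0.0, 0.0, n_particles=5, n_frames=100)
        res = tl.lateral_diffusion_msd(traj, "W", fit_window=(0.05, 0.5),
                                       n_bootstrap=10)
        assert res.D_par == 0.0

    def test_generative_D_recovered(self, flat_traj):
        res = tl.lateral_diffusion_msd(flat_traj, "W", fit_window=(1.0, 5.0))
        assert res.D_par == pytest.approx(1000.0, rel=0.10)
        assert res.uncertainty > 0

    def test_axes_with_different_D_separate(self):
        traj = synthetic_xy_traj(0.3, 0.1, seed=5)
        # mean of the two axes
        res = tl.lateral_diffusion_msd(traj, "W", fit_window=(0.1, 2.0))
        assert res.D_par == pytest.approx(0.2 * 1000, rel=0.10)
        # the axis split shows up as dominant uncertainty
        assert res.uncertainty > 0.05 * res.D_par

    def test_wrapped_coordinates_detected(self):
        traj = synthetic_xy_traj(0.2, 0.2, n_particles=3, n_frames=50)
        traj.domain = tl.SlabDomain(z_b=0.0, z_t=2.0, L_x=0.05, L_y=0.05)
        with pytest.raises(DiffusionError, match="wrap"):
            tl.lateral_diffusion_msd(traj, "W", fit_window=(0.05, 0.3))

    def test_too_few_lag_points_rejected(self):
        traj = synthetic_xy_traj(0.2, 0.2, n_particles=3, n_frames=50)
        with pytest.raises(DiffusionError, match="lag points"):
            tl.lateral_diffusion_msd(traj, "W", fit_window=(100.0, 200.0))

    def test_msd_fft_matches_direct(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(size=(64, 3)), axis=0)
        fast = _msd_fft(x)
        for m in (1, 5, 31):
            direct = np.mean((x[m:] - x[:-m]) ** 2, axis=0)
            np.testing.assert_allclose(fast[m], direct, rtol=1e-9)

    def test_no_anomalous_diffusion_loglog_slope(self, flat_traj):
        res = tl.lateral_diffusion_msd(flat_traj, "W", fit_window=(1.0, 5.0))
        xy = flat_traj.positions[:, :, :2]
        msd = (_msd_fft(xy[:, :, 0]).mean(axis=1)
               + _msd_fft(xy[:, :, 1]).mean(axis=1))
        dt = flat_traj.frame_interval
        lags = np.arange(msd.size) * dt
        sel = (lags >= 1.0) & (lags <= 5.0)
        slope = np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)[0]
        assert 0.9 <= slope <= 1.1
        assert res.D_par > 0


class TestRoundTripTimes:
    def test_deterministic_triangle_wave(self):
        # z sweeps 1.95 -> 0.05 -> 1.95 linearly with period T = 2 ns; for a
        # bin above z_* the round trip z -> z_* -> z lasts exactly the
        # waveform fraction (T/range) * (z - z_min)
        dom = tl.SlabDomain(z_b=0.0, z_t=2.0, L_x=5.0, L_y=5.0)
        t = np.arange(0.0, 40.0, 0.005)
        saw = 0.05 + 1.9 * np.abs(((t / 2.0) % 1.0) - 0.5) * 2.0
        pos = np.zeros((t.size, 1, 3))
        pos[:, 0, 2] = saw
        traj = tl.Trajectory(times=t, positions=pos,
                             species=np.array(["W"]), domain=dom)
        rt = tl.round_trip_times(traj, bins=10, z_star=0.3)
        ok = rt.defined & (rt.bin_centers > 0.4)
        assert ok.any()
        expected = (2.0 / 1.9) * (rt.bin_centers[ok] - 0.05)
        np.testing.assert_allclose(rt.tau_rt[ok], expected, atol=0.02)

    def test_unvisited_bins_masked(self, narrow_slab):
        pos = np.zeros((100, 1, 3))
        pos[:, 0, 2] = 0.5 + 0.05 * np.sin(np.arange(100.0))
        traj = tl.Trajectory(times=0.01 * np.arange(100.0), positions=pos,
                             species=np.array(["W"]), domain=narrow_slab)
        rt = tl.round_trip_times(traj, bins=20, z_star=0.45)
        far = rt.bin_centers > 1.0
        assert np.all(~rt.defined[far])
        assert np.all(np.isnan(rt.tau_rt[far]))

    def test_flat_landscape_slope_is_L_over_D(self, narrow_flat_traj):
        rt = tl.round_trip_times(narrow_flat_traj, bins=20)
        interior = slice(3, -3)
        # d tau_rt/dz = (z_t - z_b)/D = 2.0 ns/nm for L = 2 nm, D = 1
        assert np.nanmean(rt.slope[interior]) == pytest.approx(2.0, rel=0.10)

    def test_monotone_in_distance_from_reference(self, narrow_flat_traj):
        rt = tl.round_trip_times(narrow_flat_traj, bins=20)
        ok = rt.defined
        tau = rt.tau_rt[ok]
        assert np.all(np.diff(tau) > 0)  # z_* at the lower edge


class TestPerpendicularDiffusion:
    def test_flat_closed_form_identity(self):
        # analytic round-trip slope L/D with flat F gives D_zz = 1 exactly
        z = np.linspace(0.25, 4.75, 10)
        rt = tl.RoundTripProfile(bin_centers=z, tau_rt=(z - 0.25) * 5.0,
                                 counts=np.full(10, 100), z_star=0.25,
                                 slope=np.full(10, 5.0))
        F = tl.FreeEnergyProfile(bin_centers=z, F=np.zeros(10),
                                 temperature=320.0)
        D = tl.perpendicular_diffusion(rt, F, tl.AnalysisConfig())
        # integral over [0.25, 4.75] is 4.5 nm; slope 5 -> D = 4.5/5
        np.testing.assert_allclose(D.D_zz[D.valid], 4.5 / 5.0, rtol=1e-12)

    def test_flat_synthetic_recovers_D(self, narrow_flat_traj):
        rt = tl.round_trip_times(narrow_flat_traj, bins=20)
        F = tl.FreeEnergyProfile(bin_centers=rt.bin_centers,
                                 F=np.zeros(rt.bin_centers.size),
                                 temperature=320.0)
        D = tl.perpendicular_diffusion(rt, F, tl.AnalysisConfig())
        interior = slice(3, -3)
        assert np.nanmean(D.D_zz[interior]) == pytest.approx(1.0, rel=0.10)

    def test_linear_tilt_vs_mfpt_quadrature_oracle(self, linear_F_traj):
        traj, a = linear_F_traj
        b = beta(320.0)
        rt = tl.round_trip_times(traj, bins=20)
        F = tl.FreeEnergyProfile(bin_centers=rt.bin_centers,
                                 F=a * rt.bin_centers, temperature=320.0)
        D = tl.perpendicular_diffusion(rt, F, tl.AnalysisConfig())
        # oracle: tau_rt(z) = int_{z*}^{z} e^{bF(y)}/D dy * int e^{-bF} dz'
        zz = np.linspace(0.0, 2.0, 4001)
        part = np.trapezoid(np.exp(-b * a * zz), zz)
        tau = np.array([
            np.trapezoid(np.exp(b * a * np.linspace(rt.z_star, z, 500)),
                         np.linspace(rt.z_star, z, 500)) * part
            for z in rt.bin_centers])
        interior = slice(3, -3)
        np.testing.assert_allclose(rt.tau_rt[interior], tau[interior], rtol=0.12)
        assert np.nanmean(D.D_zz[interior]) == pytest.approx(1.0, rel=0.10)

    def test_two_reference_positions_agree(self, narrow_flat_traj):
        F0 = None
        results = []
        for z_star in (0.05, 0.35):
            rt = tl.round_trip_times(narrow_flat_traj, bins=20, z_star=z_star)
            if F0 is None:
                F0 = tl.FreeEnergyProfile(bin_centers=rt.bin_centers,
                                          F=np.zeros(rt.bin_centers.size),
                                          temperature=320.0)
            D = tl.perpendicular_diffusion(rt, F0, tl.AnalysisConfig())
            results.append(D.D_zz)
        # compare away from either reference position: within the slope
        # smoothing window of z_* the round-trip profile has a kink and
        # the local-polynomial derivative (hence D_zz) is unreliable
        interior = np.zeros(results[0].size, dtype=bool)
        interior[8:-3] = True
        both = np.isfinite(results[0]) & np.isfinite(results[1]) & interior
        assert both.sum() >= 9
        diff = np.abs(results[0][both] - results[1][both])
        assert np.mean(diff) < 0.1  # within estimator noise at D = 1

    def test_all_masked_slope_fails(self):
        z = np.linspace(0.0, 2.0, 5)
        rt = tl.RoundTripProfile(bin_centers=z, tau_rt=np.full(5, np.nan),
                                 counts=np.zeros(5), z_star=0.0,
                                 slope=np.full(5, np.nan))
        F = tl.FreeEnergyProfile(bin_centers=z, F=np.zeros(5), temperature=320.0)
        with pytest.raises(DiffusionError, match="no valid"):
            tl.perpendicular_diffusion(rt, F, tl.AnalysisConfig())


class TestAssignRegions:
    def test_two_population_fixture_fully_correct(self):
        dom = tl.SlabDomain(z_b=0.0, z_t=10.0, L_x=10.0, L_y=10.0)
        heads = tl.make_membrane_density(peak_separation=3.5, peak_width=0.1,
                                         z_range=(0.0, 10.0), proximal_peak=3.0)
        # lipids straddle the midplane (4.75); waters sit in reservoir/bulk
        mean_zs = {"DphPC": [3.5, 6.0], "W": [1.0, 8.0]}
        pos = np.zeros((5, 4, 3))
        pos[:, 0, 2], pos[:, 1, 2] = mean_zs["DphPC"]
        pos[:, 2, 2], pos[:, 3, 2] = mean_zs["W"]
        traj = tl.Trajectory(times=np.arange(5.0), positions=pos,
                             species=np.array(["DphPC", "DphPC", "W", "W"]),
                             domain=dom)
        labels = tl.assign_regions(traj, heads, dom)
        assert labels.tolist() == ["proximal", "distal", "reservoir_water",
                                   "bulk_water"]

    def test_missing_peaks_fail(self):
        dom = tl.SlabDomain(z_b=0.0, z_t=10.0, L_x=10.0, L_y=10.0)
        counts = np.exp(-0.5 * ((np.linspace(0, 10, 100) - 5) / 1.0) ** 2)
        edges = np.linspace(0, 10, 101)
        mono = tl.DensityProfile(bin_edges=edges, counts=counts,
                                 rho_norm=counts, rho_bulk=1.0)
        pos = np.ones((2, 1, 3))
        traj = tl.Trajectory(times=np.arange(2.0), positions=pos,
                             species=np.array(["W"]), domain=dom)
        with pytest.raises(Exception, match="local maxima"):
            tl.assign_regions(traj, mono, dom)


class TestReductionFactors:
    def test_reported_table_ratios(self):
        report = tl.diffusion_reduction_factors(lateral_diffusion_table())

        def one(kind, species, region):
            sel = report[(report.kind == kind) & (report.species == species)
                         & (report.region == region)]
            assert len(sel) == 1
            return float(sel["ratio"].iloc[0])

        # tether-induced reductions
        prox = one("tether_reduction", "DphPC", "proximal")
        assert prox == pytest.approx(290 / 87)
        assert float(f"{prox:.2g}") == 3.3
        assert one("tether_reduction", "DphPC", "distal") == pytest.approx(
            289 / 115)
        # cross-species ratio at 0%
        sp = report[(report.kind == "species_ratio")
                    & (report.densities == "0%")
                    & (report.region == "proximal")]["ratio"].iloc[0]
        assert sp == pytest.approx(290 / 256)
        assert round(sp, 2) == 1.13
        # bulk/reservoir water at 25%
        w = report[(report.kind == "water_ratio")
                   & (report.densities == "25%")]["ratio"].iloc[0]
        assert w == pytest.approx(2010 / 1236)
        assert round(w, 1) == 1.6

    def test_equal_inputs_unit_ratio(self):
        df = pd.DataFrame({
            "tether_density": ["0%", "25%"], "species": ["DphPC"] * 2,
            "region": ["proximal"] * 2, "D_par": [100.0, 100.0]})
        report = tl.diffusion_reduction_factors(df)
        assert report["ratio"].iloc[0] == 1.0

    def test_missing_pairing_fails(self):
        df = pd.DataFrame({
            "tether_density": ["0%"], "species": ["DphPC"],
            "region": ["proximal"], "D_par": [100.0]})
        with pytest.raises(DiffusionError):
            tl.diffusion_reduction_factors(df)
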