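"""Spectral dissipation, resorting, stratification and diffusivity tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turbflux import microstructure as ms
from turbflux.synthetic import generate_shear_record

from conftest import constant_eps_config


def make_record(x, fs=512.0, w=0.6, nu=1.2e-6):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) / fs
    return ms.ShearRecord(time=t, shear=x[:, None], depth=t * w,
                          temperature=np.full(x.size, 20.0),
                          fall_speed=w, sample_rate=fs, nu_constant=nu)


class TestSegmentation:
    def test_segment_count_60s_record(self):
        rec = make_record(np.random.default_rng(0).standard_normal(512 * 60))
        segs = ms.segment_shear(rec, 4.0, 0.5)
        assert len(segs) == 29  # floor((60-4)/2) + 1

    def test_record_shorter_than_segment_raises(self):
        rec = make_record(np.zeros(512 * 3))
        with pytest.raises(ValueError, match="shorter"):
            ms.segment_shear(rec, 4.0, 0.5)

    def test_segments_cover_every_sample(self):
        n = 512 * 13 + 100  # not a multiple of the hop
        rec = make_record(np.random.default_rng(1).standard_normal(n))
        segs = ms.segment_shear(rec, 4.0, 0.5)
        covered = np.zeros(n, dtype=bool)
        fs, w = rec.sample_rate, rec.fall_speed
        for s in segs:
            if s.probe:
                continue
            i0 = int(round(s.depth_span[0] / w * fs))
            covered[i0:i0 + s.shear.size] = True
        assert covered.all()


class TestShearSpectrum:
    def test_sine_peak_position_and_parseval(self):
        fs, w, a, f0 = 512.0, 0.6, 0.03, 25.0
        t = np.arange(int(fs * 4)) / fs
        rec = make_record(a * np.sin(2 * np.pi * f0 * t), fs=fs, w=w)
        seg = ms.segment_shear(rec, 4.0, 0.0)[0]
        spec = ms.shear_spectrum(seg)
        k_peak = spec.k[np.argmax(spec.phi)]
        assert k_peak == pytest.approx(f0 / w, rel=0.01)
        assert np.trapezoid(spec.phi, spec.k) == pytest.approx(a ** 2 / 2, rel=0.01)

    def test_doubling_fall_speed_halves_wavenumber(self):
        fs, a, f0 = 512.0, 0.03, 25.0
        t = np.arange(int(fs * 4)) / fs
        x = a * np.sin(2 * np.pi * f0 * t)
        peaks = []
        for w in (0.6, 1.2):
            seg = ms.segment_shear(make_record(x, fs=fs, w=w), 4.0, 0.0)[0]
            spec = ms.shear_spectrum(seg)
            peaks.append(spec.k[np.argmax(spec.phi)])
        assert peaks[0] == pytest.approx(2 * peaks[1], rel=1e-6)

    def test_white_noise_integral_matches_variance(self):
        x = np.random.default_rng(2).standard_normal(2 ** 17)
        rec = make_record(x)
        seg = ms.segment_shear(rec, 2 ** 17 / 512.0, 0.0)[0]
        spec = ms.shear_spectrum(seg)
        assert np.trapezoid(spec.phi, spec.k) == pytest.approx(
            np.var(seg.shear), rel=0.01)

    def test_parseval_windowed_corrected_identity(self):
        # integral of the spectrum equals the window-power-corrected
        # variance of the detrended segment far inside 1%
        x = np.random.default_rng(3).standard_normal(2048)
        seg = ms.segment_shear(make_record(x), 4.0, 0.0)[0]
        spec = ms.shear_spectrum(seg)
        assert np.sum(spec.phi) * np.diff(spec.k)[0] == pytest.approx(
            spec.variance, rel=1e-3)

    def test_zero_fall_speed_rejected(self):
        with pytest.raises(ValueError):
            make_record(np.zeros(2048), w=0.0)


class TestNasmyth:
    @pytest.mark.parametrize("eps", [1e-10, 1e-9, 1e-8, 1e-7, 1e-6])
    def test_normalization_recovers_epsilon(self, eps):
        # defining property: 7.5 nu * integral(Phi_N dk) = eps
        nu = 1.2e-6
        k = np.logspace(-3, 5, 40000)
        integral = np.trapezoid(ms.nasmyth_spectrum(eps, nu, k), k)
        assert 7.5 * nu * integral == pytest.approx(eps, rel=0.03)

    def test_inertial_subrange_slope_one_third(self):
        eps, nu = 1e-8, 1.2e-6
        k1, k2 = 0.5, 2.0  # far below the roll-off for this eps
        ratio = (ms.nasmyth_spectrum(eps, nu, np.array([k1]))[0]
                 / ms.nasmyth_spectrum(eps, nu, np.array([k2]))[0])
        assert ratio == pytest.approx((k1 / k2) ** (1 / 3), rel=0.01)

    def test_rolloff_scales_as_eps_quarter_power(self):
        nu = 1.2e-6
        k = np.logspace(-1, 4, 200000)
        k_pk1 = k[np.argmax(ms.nasmyth_spectrum(1e-9, nu, k))]
        k_pk2 = k[np.argmax(ms.nasmyth_spectrum(1e-8, nu, k))]
        assert k_pk2 / k_pk1 == pytest.approx(10 ** 0.25, rel=0.01)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            ms.nasmyth_spectrum(0.0, 1e-6, np.array([1.0]))
        with pytest.raises(ValueError):
            ms.nasmyth_spectrum(1e-8, 1e-6, np.array([0.0]))


class TestEstimateEpsilon:
    def test_noise_free_nasmyth_spectrum_recovered(self):
        eps, nu = 1e-8, 1.2e-6
        k = np.linspace(0.25, 400.0, 1600)
        spec = ms.ShearSpectrum(k=k, phi=ms.nasmyth_spectrum(eps, nu, k),
                                nu=nu, depth_center=100.0,
                                depth_span=(99.0, 101.0),
                                variance=eps / (7.5 * nu))
        est, flag = ms.estimate_epsilon(spec)
        assert flag == "accepted"
        assert est == pytest.approx(eps, rel=0.05)

    def test_flat_spectrum_fails_consistency_qc(self):
        nu = 1.2e-6
        k = np.linspace(0.25, 400.0, 1600)
        spec = ms.ShearSpectrum(k=k, phi=np.full_like(k, 1e-6), nu=nu,
                                depth_center=100.0, depth_span=(99.0, 101.0),
                                variance=1.0)
        _, flag = ms.estimate_epsilon(spec)
        assert flag == "rejected"

    @pytest.mark.parametrize("eps", [1e-10, 1e-8, 1e-6])
    def test_record_level_recovery(self, eps):
        cfg = constant_eps_config(seed=11, eps=eps, record_seconds=20.0)
        rec = generate_shear_record(cfg, 0, n_probes=1)
        prof = ms.dissipation_profile(rec)
        assert np.nanmedian(prof.epsilon) == pytest.approx(eps, rel=0.5)


class TestCombine:
    def grid_profile(self, eps_values, flags=None):
        n = len(eps_values)
        eps = np.asarray(eps_values, dtype=float)
        flags = np.asarray(flags if flags is not None
                           else np.where(np.isfinite(eps), "accepted", "rejected"),
                           dtype=object)
        return ms.DissipationProfile(depth=np.arange(n, dtype=float),
                                     epsilon=eps, nu=np.full(n, 1.2e-6),
                                     flag=flags)

    def test_mean_of_two_casts(self):
        combined = ms.combine_probes_and_casts(
            [self.grid_profile([1e-8]), self.grid_profile([4e-8])])
        assert combined.epsilon[0] == pytest.approx(2.5e-8)

    def test_rejected_cast_leaves_survivor(self):
        combined = ms.combine_probes_and_casts(
            [self.grid_profile([np.nan]), self.grid_profile([4e-8])])
        assert combined.epsilon[0] == pytest.approx(4e-8)
        assert combined.flag[0] == "accepted"

    def test_all_rejected_stays_missing(self):
        combined = ms.combine_probes_and_casts(
            [self.grid_profile([np.nan]), self.grid_profile([np.nan])])
        assert np.isnan(combined.epsilon[0])
        assert combined.flag[0] == "rejected"

    def test_identical_casts_identity(self):
        p = self.grid_profile([1e-8, 2e-8, np.nan])
        combined = ms.combine_probes_and_casts([p, p])
        assert np.allclose(combined.epsilon[:2], p.epsilon[:2])

    def test_disjoint_grids_rejected(self):
        a = self.grid_profile([1e-8, 2e-8])
        b = self.grid_profile([1e-8, 2e-8, 3e-8])
        with pytest.raises(ValueError, match="grid"):
            ms.combine_probes_and_casts([a, b])


class TestThorpeResort:
    def test_stable_profile_is_identity(self):
        depth = np.arange(10.0)
        sigma = 24.0 + 0.01 * depth
        st_ = ms.thorpe_resort(depth, sigma)
        assert np.array_equal(st_.sigma_resorted, sigma)
        assert np.allclose(st_.thorpe_displacement, 0.0)

    def test_three_point_inversion(self):
        st_ = ms.thorpe_resort(np.array([0.0, 1.0, 2.0]),
                               np.array([24.1, 24.0, 24.2]))
        assert np.allclose(st_.sigma_resorted, [24.0, 24.1, 24.2])
        assert np.allclose(st_.thorpe_displacement, [1.0, -1.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_matches_naive_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 200))
        depth = np.cumsum(rng.uniform(0.5, 2.0, n))
        sigma = rng.normal(25.0, 0.5, n)
        st_ = ms.thorpe_resort(depth, sigma)
        assert np.array_equal(st_.sigma_resorted, np.sort(sigma))
        assert np.all(np.diff(st_.sigma_resorted) >= 0)
        assert st_.thorpe_displacement.sum() == pytest.approx(0.0, abs=1e-9)
        assert np.array_equal(np.sort(st_.sigma_resorted), np.sort(sigma))

    def test_nan_values_kept_as_gaps(self):
        depth = np.arange(5.0)
        sigma = np.array([24.2, np.nan, 24.0, 24.1, 24.3])
        st_ = ms.thorpe_resort(depth, sigma)
        assert np.isnan(st_.sigma_resorted[1])
        ok = np.isfinite(st_.sigma_resorted)
        assert np.all(np.diff(st_.sigma_resorted[ok]) >= 0)


class TestBuoyancyFrequency:
    def test_linear_density_closed_form(self):
        depth = np.arange(0.0, 100.0)
        st_ = ms.thorpe_resort(depth, 24.0 + 0.01 * depth)
        ms.buoyancy_frequency(st_, smoothing_scale=10.0)
        expected = 9.81 / 1027.0 * 0.01
        assert np.allclose(st_.n2, expected, rtol=1e-6)

    def test_homogeneous_profile_floored_and_flagged(self):
        depth = np.arange(0.0, 50.0)
        st_ = ms.thorpe_resort(depth, np.full(50, 24.0))
        ms.buoyancy_frequency(st_, n2_floor=1e-7)
        assert np.all(st_.n2 == 1e-7)
        assert np.all(st_.n2_flag == "floor")

    def test_too_few_points_rejected(self):
        st_ = ms.thorpe_resort(np.array([0.0, 1.0]), np.array([24.0, 24.1]))
        with pytest.raises(ValueError):
            ms.buoyancy_frequency(st_)


class TestMixedLayerDepth:
    def test_gradual_profile_interpolated(self):
        # uniform to 37 m, then +0.001 kg m^-3 per m: threshold at 37+30 m
        depth = np.arange(0.0, 120.0)
        sigma = 24.0 + np.where(depth > 37.0, 0.001 * (depth - 37.0), 0.0)
        mld, reached = ms.mixed_layer_depth(depth, sigma)
        assert reached
        assert mld == pytest.approx(67.0, abs=1.0)

    def test_step_profile(self):
        depth = np.arange(0.0, 80.0)
        sigma = np.where(depth >= 40.0, 24.5, 24.0)
        mld, reached = ms.mixed_layer_depth(depth, sigma)
        assert reached
        assert mld == pytest.approx(40.0, abs=1.0)

    def test_criterion_never_met_flags_deepest(self):
        depth = np.arange(0.0, 50.0)
        mld, reached = ms.mixed_layer_depth(depth, np.full(50, 24.0))
        assert not reached
        assert mld == depth[-1]


class TestOsborn:
    def strat(self, n2_value, mld=20.0, n=40):
        depth = np.arange(float(n)) * 5.0 + 2.5
        st_ = ms.StratificationProfile(
            depth=depth, sigma_observed=np.zeros(n),
            sigma_resorted=np.zeros(n), thorpe_displacement=np.zeros(n),
            n2=np.full(n, n2_value), n2_flag=np.full(n, "ok", dtype=object),
            mld=mld)
        return st_

    def diss(self, eps_value, n=40):
        depth = np.arange(float(n)) * 5.0 + 2.5
        eps = np.full(n, eps_value)
        return ms.DissipationProfile(depth=depth, epsilon=eps,
                                     nu=np.full(n, 1.2e-6),
                                     flag=np.full(n, "accepted", dtype=object))

    def test_hotspot_magnitude(self):
        # eps 1e-7, N2 2e-5 -> K = 1e-3 m2/s, the hotspot order of magnitude
        prof = ms.osborn_diffusivity(self.diss(1e-7), self.strat(2e-5))
        below = prof.depth > 20.0
        assert np.allclose(prof.k_rho[below], 1e-3)

    def test_open_ocean_magnitude(self):
        prof = ms.osborn_diffusivity(self.diss(1e-8), self.strat(1e-4))
        below = prof.depth > 20.0
        assert np.allclose(prof.k_rho[below], 2e-5)

    def test_mixed_layer_masked_regardless_of_eps(self):
        prof = ms.osborn_diffusivity(self.diss(1e-6), self.strat(1e-5, mld=50.0))
        above = prof.depth <= 50.0
        assert np.all(np.isnan(prof.k_rho[above]))
        assert np.all(prof.mask_reason[above] == "mixed-layer")

    def test_monotone_in_epsilon(self):
        k1 = ms.osborn_diffusivity(self.diss(1e-9), self.strat(1e-5)).k_rho
        k2 = ms.osborn_diffusivity(self.diss(1e-8), self.strat(1e-5)).k_rho
        below = ~np.isnan(k1)
        assert np.all(k2[below] > k1[below])
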