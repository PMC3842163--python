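"""Generator contracts: closed forms when noiseless, calibrated noise,
seed reproducibility, and the coupled-kinetics simulator."""

import numpy as np
import pytest

import warmkit as wk


class TestSimulateWashoutTac:
    def test_noiseless_is_exact_mono_exponential(self):
        sched = wk.uniform_frame_schedule(600.0, 15.0)
        tac = wk.simulate_washout_tac(wk.SimulationSpec(50.0, 0.92, 0.0, sched, 0))
        expected = 50.0 * np.exp(-0.92 * tac.frame_mid_times / 60.0)
        np.testing.assert_allclose(tac.values, expected, rtol=1e-12)

    def test_noise_sd_matches_contract(self):
        # 10,000 replicate draws of one frame: empirical SD/mean = 0.20 +- 0.01
        sched = [(0.0, 30.0)]
        draws = np.array(
            [
                wk.simulate_washout_tac(wk.SimulationSpec(100.0, 0.92, 0.2, sched, seed)).values[0]
                for seed in range(10_000)
            ]
        )
        clean = 100.0 * np.exp(-0.92 * 15.0 / 60.0)
        assert draws.std() / clean == pytest.approx(0.20, abs=0.01)
        assert draws.mean() == pytest.approx(clean, rel=0.01)

    def test_seed_reproducibility(self):
        spec = wk.SimulationSpec(100.0, 0.98, 0.2, wk.uniform_frame_schedule(300, 10), 42)
        a = wk.simulate_washout_tac(spec)
        b = wk.simulate_washout_tac(spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            wk.SimulationSpec(washout_rate=-1.0)
        with pytest.raises(ValueError):
            wk.SimulationSpec(noise_fraction=-0.1)
        with pytest.raises(ValueError):
            wk.SimulationSpec(frame_schedule=[(0, 10), (5, 15)])


class TestSimulateBolusInput:
    def test_zero_scale_gives_zero_input(self):
        aif = wk.simulate_bolus_input(scale=0.0)
        assert np.all(aif.concentrations == 0.0)

    def test_peak_at_requested_time(self):
        aif = wk.simulate_bolus_input(peak_time=30.0, sample_step_s=1.0)
        t_peak = aif.sample_times[np.argmax(aif.concentrations)]
        assert abs(t_peak - 30.0) <= 1.0  # gamma-variate mode = peak_time

    def test_linearity_in_scale(self):
        a = wk.simulate_bolus_input(scale=1.0)
        b = wk.simulate_bolus_input(scale=2.0)
        np.testing.assert_allclose(b.concentrations, 2.0 * a.concentrations, rtol=1e-12)

    def test_nonnegative_unimodal_finite(self):
        aif = wk.simulate_bolus_input(peak_time=20.0, shape=8.0)
        c = aif.concentrations
        assert np.all(c >= 0)
        i = int(np.argmax(c))
        # unimodal above a floor excluding subnormal round-off in the far tail
        floor = 1e-12 * c[i]
        assert np.all(np.diff(c[:i]) >= 0)
        tail = c[i:][c[i:] > floor]
        assert np.all(np.diff(tail) <= 0)
        assert np.isfinite(np.trapezoid(c, aif.sample_times))


class TestOneTissueResponse:
    def test_matches_analytic_convolution_for_exponential_input(self):
        # c_a = e^(-a t): m(t) = K1 (e^(-k t) - e^(-a t))/(a - k), rates per min
        t = np.arange(0.0, 600.0, 0.5)
        a, k, K1 = 1.5, 0.4, 0.7
        ca = np.exp(-a * t / 60.0)
        m = wk.one_tissue_response(t, ca, K1, k)
        expected = K1 * (np.exp(-k * t / 60.0) - np.exp(-a * t / 60.0)) / (a - k)
        # solver is exact for piecewise-linear input; the residual is the
        # O(h^2) chord error of sampling the exponential at 0.5 s
        np.testing.assert_allclose(m, expected, atol=2e-5 * expected.max())

    def test_zero_washout_reduces_to_integral(self):
        t = np.arange(0.0, 300.0, 0.5)
        ca = np.exp(-t / 50.0)
        m = wk.one_tissue_response(t, ca, 1.0, 0.0)
        expected = np.concatenate(
            [[0.0], np.cumsum(np.diff(t / 60.0) * (ca[:-1] + ca[1:]) / 2.0)]
        )
        np.testing.assert_allclose(m, expected, rtol=1e-9, atol=1e-12)


class TestSimulateSrtmPair:
    def test_zero_binding_unit_flow_gives_identical_curves(self, sharp_bolus, srtm_schedule):
        roi, ref = wk.simulate_srtm_pair(sharp_bolus, 0.3, 0.15, 1.0, 0.0, srtm_schedule)
        np.testing.assert_allclose(roi.values, ref.values, rtol=1e-12)

    def test_tail_log_slope_is_minus_k2a(self, sharp_bolus, srtm_schedule):
        r1, k2nd, bp = 0.8, 0.15, 0.5
        roi, _ = wk.simulate_srtm_pair(sharp_bolus, 0.3, k2nd, r1, bp, srtm_schedule)
        k2a = r1 * k2nd / (1.0 + bp)
        # after the input has cleared, log(roi) is affine in t with slope -k2a
        tail = roi.frame_mid_times > 1200.0
        slope = np.polyfit(roi.frame_mid_times[tail] / 60.0, np.log(roi.values[tail]), 1)[0]
        assert slope == pytest.approx(-k2a, rel=1e-3)

    def test_linearity_in_k1nd(self, sharp_bolus, srtm_schedule):
        roi1, ref1 = wk.simulate_srtm_pair(sharp_bolus, 0.3, 0.15, 0.8, 0.3, srtm_schedule)
        roi2, ref2 = wk.simulate_srtm_pair(sharp_bolus, 0.6, 0.15, 0.8, 0.3, srtm_schedule)
        np.testing.assert_allclose(roi2.values, 2.0 * roi1.values, rtol=1e-12)
        np.testing.assert_allclose(ref2.values, 2.0 * ref1.values, rtol=1e-12)

    def test_reference_noise_can_differ(self, sharp_bolus, srtm_schedule):
        roi, ref = wk.simulate_srtm_pair(
            sharp_bolus, 0.3, 0.15, 0.8, 0.3, srtm_schedule,
            noise_fraction=0.2, seed=7, ref_noise_fraction=0.0,
        )
        roi_clean, ref_clean = wk.simulate_srtm_pair(sharp_bolus, 0.3, 0.15, 0.8, 0.3, srtm_schedule)
        np.testing.assert_allclose(ref.values, ref_clean.values, rtol=1e-12)
        assert not np.allclose(roi.values, roi_clean.values)


class TestSimulatePhantom:
    def make_spec(self, labels, noise=0.0, seed=0):
        regions = (
            wk.PhantomRegion(1, r1=1.0, k2nd_per_min=0.3, bp_nd=0.0),
            wk.PhantomRegion(2, r1=1.2, k2nd_per_min=0.3, bp_nd=0.8),
        )
        sched = wk.uniform_frame_schedule(600.0, 10.0)
        return wk.PhantomSpec(labels, regions, 1, sched, noise_fraction=noise, seed=seed)

    def test_single_region_reference_has_zero_bp_truth(self):
        labels = np.ones((3, 3, 1), dtype=int)
        regions = (wk.PhantomRegion(1, r1=1.0, k2nd_per_min=0.3, bp_nd=0.0),)
        ph = wk.simulate_phantom(
            wk.PhantomSpec(labels, regions, 1, wk.uniform_frame_schedule(600, 10))
        )
        assert np.all(ph.bp_map == 0.0)

    def test_noisy_regional_mean_near_noiseless_curve(self, two_region_labels):
        ph = wk.simulate_phantom(self.make_spec(two_region_labels, noise=0.2, seed=3))
        clean = wk.simulate_phantom(self.make_spec(two_region_labels))
        for lab in (1, 2):
            noisy_mean = ph.region_mean_tac(lab).values
            clean_mean = clean.region_mean_tac(lab).values
            n_vox = np.count_nonzero(two_region_labels == lab)
            # proportional noise: SE of the regional mean is 0.2/sqrt(n) per frame
            z = (noisy_mean - clean_mean) / (0.2 * clean_mean / np.sqrt(n_vox))
            assert np.all(np.abs(z) < 5.0)

    def test_fixed_seed_bit_identical(self, two_region_labels):
        a = wk.simulate_phantom(self.make_spec(two_region_labels, noise=0.2, seed=11))
        b = wk.simulate_phantom(self.make_spec(two_region_labels, noise=0.2, seed=11))
        np.testing.assert_array_equal(a.data, b.data)

    def test_duplicate_labels_rejected(self, two_region_labels):
        regions = (wk.PhantomRegion(1), wk.PhantomRegion(1))
        with pytest.raises(ValueError, match="duplicate"):
            wk.PhantomSpec(two_region_labels, regions, 1, wk.uniform_frame_schedule(600, 10))
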