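"""WARM estimators: closed-form recovery, estimator equivalence,
invariances, and the voxelwise parametric map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import warmkit as wk
from warmkit.exceptions import DegenerateSignalError, InsufficientDataError

from conftest import make_washout_curve, washout_seg


def closed_form_bp(r1, k2nd, k2a):
    return r1 * k2nd / k2a - 1.0


GRID = [
    (r1, k2nd, k2a)
    for r1 in (0.5, 0.8, 1.0, 1.2, 2.0)
    for k2nd in (0.05, 0.2, 0.92)
    for k2a in (0.03, 0.1, 0.98)
]


class TestOperational:
    def test_identity_gives_zero_for_all_truncations(self):
        wc = make_washout_curve(0.3)
        res = wk.warm_bp_operational(wc, wc)
        assert res.bp_nd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.bp_trajectory, 0.0, atol=1e-12)

    @pytest.mark.parametrize("r1,k2nd,k2a", [(1.0, 0.92, 0.98), (1.2, 0.2, 0.1)])
    def test_closed_form_on_noiseless_pairs(self, r1, k2nd, k2a):
        roi = make_washout_curve(k2a, initial_value=100.0 * r1)
        ref = make_washout_curve(k2nd, initial_value=100.0)
        res = wk.warm_bp_operational(roi, ref)
        expected = closed_form_bp(r1, k2nd, k2a)
        assert res.r1_used == pytest.approx(r1, rel=1e-12)
        # constant in T on mono-exponential input (trapezoid exact on linear logs)
        np.testing.assert_allclose(res.bp_trajectory, expected, rtol=1e-9)

    def test_trajectory_ends_at_bp(self):
        roi = make_washout_curve(0.5, initial_value=80.0)
        ref = make_washout_curve(0.4)
        res = wk.warm_bp_operational(roi, ref)
        assert res.bp_trajectory[-1] == res.bp_nd
        assert res.dvr == pytest.approx(1.0 + res.bp_nd)

    def test_flat_roi_curve_raises(self):
        flat = make_washout_curve(0.0)
        ref = make_washout_curve(0.3)
        with pytest.raises(DegenerateSignalError, match="no washout signal"):
            wk.warm_bp_operational(flat, ref)

    def test_too_few_frames_raises(self):
        t = np.array([0.0, 30.0])
        wc = wk.WashoutCurve(t, np.exp(-0.005 * t), initial_value=10.0)
        with pytest.raises(InsufficientDataError):
            wk.warm_bp_operational(wc, wc)

    @given(scale=st.floats(min_value=1e-2, max_value=1e2))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_scale_invariance(self, scale):
        roi = make_washout_curve(0.6, initial_value=120.0 * scale)
        ref = make_washout_curve(0.4, initial_value=100.0 * scale)
        res = wk.warm_bp_operational(roi, ref)
        assert res.bp_nd == pytest.approx(closed_form_bp(1.2, 0.4, 0.6), rel=1e-9)

    def test_monotone_decreasing_in_roi_washout_rate(self):
        ref = make_washout_curve(0.4)
        bps = [
            wk.warm_bp_operational(make_washout_curve(k2a), ref).bp_nd
            for k2a in (0.2, 0.3, 0.5, 0.8)
        ]
        assert all(a > b for a, b in zip(bps, bps[1:]))


class TestAllometric:
    def test_identity_slope_one(self):
        wc = make_washout_curve(0.3)
        params = wk.warm_bp_allometric(wc, wc, r1=1.0)
        assert params.bp_nd == pytest.approx(0.0, abs=1e-12)

    def test_slope_is_rate_ratio_on_noiseless_pairs(self):
        k2nd, k2a, r1 = 0.2, 0.5, 1.3
        roi = make_washout_curve(k2a)
        ref = make_washout_curve(k2nd)
        params = wk.warm_bp_allometric(roi, ref, r1=r1)
        assert params.dvr == pytest.approx(r1 * k2nd / k2a, rel=1e-12)

    def test_flat_regressor_raises(self):
        flat = make_washout_curve(0.0)
        ref = make_washout_curve(0.3)
        with pytest.raises(DegenerateSignalError):
            wk.warm_bp_allometric(flat, ref, r1=1.0)

    def test_noisy_slope_unbiased_over_seeds(self, fig1_schedule):
        # 500 seeds: the mean slope stays within 2 SE of the noiseless slope
        k2nd, k2a = 0.92, 0.98
        slopes = []
        for seed in range(500):
            ref = wk.simulate_washout_tac(wk.SimulationSpec(100, k2nd, 0.2, fig1_schedule, 2 * seed))
            roi = wk.simulate_washout_tac(wk.SimulationSpec(100, k2a, 0.2, fig1_schedule, 2 * seed + 1))
            try:
                wr = wk.to_washout_curve(roi, washout_seg(roi))
                wf = wk.to_washout_curve(ref, washout_seg(ref))
                slopes.append(wk.warm_bp_allometric(wr, wf, r1=1.0).dvr)
            except (DegenerateSignalError, InsufficientDataError):
                continue
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - k2nd / k2a) < 2 * se + 0.02


class TestEquivalenceAndGrid:
    @pytest.mark.parametrize("r1,k2nd,k2a", GRID)
    def test_operational_matches_closed_form_and_allometric(self, r1, k2nd, k2a):
        roi = make_washout_curve(k2a, initial_value=100.0 * r1)
        ref = make_washout_curve(k2nd, initial_value=100.0)
        expected = closed_form_bp(r1, k2nd, k2a)
        op = wk.warm_bp_operational(roi, ref)
        al = wk.warm_bp_allometric(roi, ref, r1=r1)
        np.testing.assert_allclose(op.bp_trajectory, expected, rtol=1e-6, atol=1e-9)
        assert op.bp_nd == pytest.approx(al.bp_nd, abs=1e-6 * max(1.0, abs(expected)))


class TestK2a:
    def test_exact_log_linear_rate(self):
        wc = make_washout_curve(0.5)
        assert wk.warm_k2a(wc) == pytest.approx(0.5, rel=1e-12)

    def test_constant_curve_returns_zero(self):
        assert wk.warm_k2a(make_washout_curve(0.0)) == 0.0

    def test_noisy_mean_recovers_truth(self, fig1_schedule):
        k = 0.92
        est = []
        for seed in range(500):
            tac = wk.simulate_washout_tac(wk.SimulationSpec(100, k, 0.2, fig1_schedule, seed))
            try:
                est.append(wk.warm_k2a(wk.to_washout_curve(tac, washout_seg(tac))))
            except (DegenerateSignalError, InsufficientDataError):
                continue
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - k) < 3 * se + 0.01


class TestPointwiseVsOperational:
    def test_integration_reduces_variance(self, fig1_schedule):
        op, pw = [], []
        for seed in range(200):
            ref = wk.simulate_washout_tac(wk.SimulationSpec(100, 0.92, 0.2, fig1_schedule, 2 * seed))
            roi = wk.simulate_washout_tac(wk.SimulationSpec(100, 0.98, 0.2, fig1_schedule, 2 * seed + 1))
            try:
                wr = wk.to_washout_curve(roi, washout_seg(roi))
                wf = wk.to_washout_curve(ref, washout_seg(ref))
                op.append(wk.warm_bp_operational(wr, wf).bp_nd)
                pw.append(wk.warm_bp_pointwise(wr, wf).bp_nd)
            except (DegenerateSignalError, InsufficientDataError):
                continue
        assert np.var(op, ddof=1) < np.var(pw, ddof=1)


class TestParametricMap:
    def make_phantom(self, labels, noise=0.0, seed=0):
        regions = (
            wk.PhantomRegion(1, r1=1.0, k2nd_per_min=0.3, bp_nd=0.0),
            wk.PhantomRegion(2, r1=1.2, k2nd_per_min=0.3, bp_nd=0.8),
        )
        return wk.simulate_phantom(
            wk.PhantomSpec(labels, regions, 1, wk.uniform_frame_schedule(600.0, 10.0),
                           noise_fraction=noise, seed=seed)
        )

    def phantom_seg(self, ph):
        t0 = ph.frame_mid_times[0]
        return wk.PhaseSegmentation(0.0, (0.0, t0), t0, 1.0, t0, ph.frame_ends[-1])

    def test_reference_only_phantom_maps_to_zero(self):
        labels = np.ones((3, 3, 1), dtype=int)
        regions = (wk.PhantomRegion(1, r1=1.0, k2nd_per_min=0.3, bp_nd=0.0),)
        ph = wk.simulate_phantom(
            wk.PhantomSpec(labels, regions, 1, wk.uniform_frame_schedule(600, 10))
        )
        bp_map, n_failed = wk.warm_parametric_map(
            ph.data, ph.frame_starts, ph.frame_ends, ph.reference_tac(), self.phantom_seg(ph)
        )
        assert n_failed == 0
        np.testing.assert_allclose(bp_map, 0.0, atol=1e-12)

    def test_noiseless_two_region_phantom_matches_closed_form(self, two_region_labels):
        ph = self.make_phantom(two_region_labels)
        bp_map, n_failed = wk.warm_parametric_map(
            ph.data, ph.frame_starts, ph.frame_ends, ph.reference_tac(), self.phantom_seg(ph)
        )
        assert n_failed == 0
        np.testing.assert_allclose(bp_map[two_region_labels == 2], 0.8, atol=1e-6)
        np.testing.assert_allclose(bp_map[two_region_labels == 1], 0.0, atol=1e-6)

    def test_noisy_phantom_regional_mean_within_3se(self, two_region_labels):
        ph = self.make_phantom(two_region_labels, noise=0.2, seed=5)
        bp_map, _ = wk.warm_parametric_map(
            ph.data, ph.frame_starts, ph.frame_ends, ph.reference_tac(), self.phantom_seg(ph)
        )
        vals = bp_map[two_region_labels == 2]
        vals = vals[np.isfinite(vals)]
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.8) < 3 * se + 0.05

    def test_frame_mismatch_raises(self, two_region_labels):
        ph = self.make_phantom(two_region_labels)
        with pytest.raises(ValueError, match="frame schedule"):
            wk.warm_parametric_map(
                ph.data, ph.frame_starts[:-1], ph.frame_ends[:-1],
                ph.reference_tac(), self.phantom_seg(ph),
            )
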