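import numpy as np
import pytest

import warmkit as wk


def make_washout_curve(rate_per_min, duration_s=600.0, frame_s=5.0, initial_value=100.0):
    """Noiseless mono-exponential WashoutCurve with times from 0."""
    t = np.arange(0.0, duration_s, frame_s)
    return wk.WashoutCurve(t, np.exp(-rate_per_min * t / 60.0), initial_value=initial_value)


def washout_seg(tac, duration_T=None):
    """Segmentation whose washout spans the whole TAC (pure-washout input)."""
    t0 = tac.frame_mid_times[0]
    end = tac.frame_mid_times[-1] if duration_T is None else duration_T
    return wk.PhaseSegmentation(
        arterial_end=0.0,
        peak_window=(0.0, t0),
        peak_time=t0,
        peak_value=float(tac.values[0]),
        washout_start=t0,
        washout_end=end,
    )


@pytest.fixture
def fig1_schedule():
    return wk.uniform_frame_schedule(600.0, 5.0)


@pytest.fixture
def sharp_bolus():
    """A rapidly cleared gamma-variate bolus (essentially gone by ~1 min)."""
    return wk.simulate_bolus_input(peak_time=10.0, scale=100.0, shape=40.0,
                                   duration_s=3600.0, sample_step_s=0.25)


@pytest.fixture
def srtm_schedule():
    return wk.default_frame_schedule()


@pytest.fixture
def two_region_labels():
    labels = np.zeros((4, 4, 2), dtype=int)
    labels[:2] = 1
    labels[2:] = 2
    return labels
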