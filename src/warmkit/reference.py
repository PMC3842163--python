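"""Flow-adjusted reference curves, flow-devolved SUVR, and data-driven
reference-region detection via the washout index Θ.

A measured reference curve m_ND(t) only represents the non-displaceable
washout of a voxel whose blood flow matches the reference region's.  For a
voxel with relative flow R1, the washout the voxel *would* show in the
absence of binding is the power-law adjusted curve

    n_ND(t) = n_ND(0) [m_ND(t) / m_ND(0)]^R1,

since mono-exponential washout rates scale with flow.  The flow-devolved
BP_ND is then the late-window AUC ratio of the measured voxel curve to its
simulated flow-adjusted reference.

The washout index Θ quantifies how completely a voxel washes out over the
scan: Θ = ∫ (1 - m*(t)/m*(t0)) dt over the washout interval.  Θ has units
of time, is bounded by the washout horizon, and approaches that horizon for
fast, unhindered washout — so voxels with Θ near the scan duration are
reference-region candidates (default criterion: Θ > 1660 s with
T = 1890 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSignalError
from .tac import PhaseSegmentation, TimeActivityCurve, to_washout_curve, window_auc
from .warm import _cumtrapz

__all__ = [
    "WashoutIndex",
    "ReferenceCandidate",
    "flow_adjusted_reference",
    "flow_devolved_bp",
    "washout_index",
    "detect_reference_region",
]

#: published selection constants: Θ threshold and scan duration, seconds
DEFAULT_THETA_THRESHOLD_S = 1660.0
DEFAULT_DURATION_T_S = 1890.0


@dataclass(frozen=True)
class WashoutIndex:
    """Washout completeness index Θ (seconds) over [washout_start, duration_T]."""

    theta: float
    duration_T: float
    washout_start: float

    def __post_init__(self):
        horizon = self.duration_T - self.washout_start
        if horizon <= 0:
            raise ValueError("duration_T must exceed washout_start")
        if not (0.0 <= self.theta <= horizon + 1e-9):
            raise ValueError("theta must lie in [0, duration_T - washout_start]")


@dataclass(frozen=True)
class ReferenceCandidate:
    """Voxels whose Θ exceeds the threshold, with summary statistics."""

    mask: np.ndarray
    theta_threshold: float
    voxel_count: int
    mean_theta: float
    theta_map: np.ndarray


def flow_adjusted_reference(
    ref_tac: TimeActivityCurve,
    seg: PhaseSegmentation,
    r1: float,
    n0: float,
) -> TimeActivityCurve:
    """Simulated reference curve for a voxel with relative flow ``r1``.

    Returns n_ND(t) = n0 (m_ND(t)/m_ND(t0))^r1 on the reference washout
    frames; non-positive reference frames are excluded with a warning from
    the normalization step.
    """
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    wc = to_washout_curve(ref_tac, seg)
    times = wc.times_from_t0 + seg.washout_start
    # recover frame durations of the retained frames from the source TAC
    durs = np.interp(times, ref_tac.frame_mid_times, ref_tac.frame_durations)
    values = n0 * wc.remaining_fraction**r1
    return TimeActivityCurve(times, durs, values, label=f"{ref_tac.label}:flow-adjusted")


def flow_devolved_bp(
    roi_tac: TimeActivityCurve,
    simulated_ref: TimeActivityCurve,
    window: tuple = (2400.0, 3600.0),
) -> float:
    """Flow-devolved BP_ND: AUC(ROI)/AUC(flow-adjusted reference) - 1.

    ``window`` is (start, end) in seconds, default the late 40–60 min
    steady-state window.
    """
    start, end = window
    num = window_auc(roi_tac, start, end)
    den = window_auc(simulated_ref, start, end)
    if den == 0.0:
        raise DegenerateSignalError("zero reference integral in the window")
    return num / den - 1.0


def washout_index(tac: TimeActivityCurve, seg: PhaseSegmentation, duration_T: float | None = None) -> WashoutIndex:
    """Washout index Θ = ∫_{t0}^{T} [1 - m*(t)/m*(t0)] dt.

    ``duration_T`` (absolute end time, seconds) defaults to
    ``seg.washout_end``; Θ is clamped to [0, T - t0].
    """
    if duration_T is None:
        duration_T = seg.washout_end
    t0 = seg.washout_start
    times = tac.frame_mid_times
    keep = (times >= t0) & (times <= duration_T)
    if np.count_nonzero(keep) < 2:
        raise DegenerateSignalError("degenerate curve: washout has no extent")
    t = times[keep]
    v = tac.values[keep]
    v0 = float(np.interp(t0, times, tac.values))
    if v0 <= 0:
        raise DegenerateSignalError("non-positive washout origin")
    if abs(t[0] - t0) > 1e-9:
        t = np.concatenate([[t0], t])
        v = np.concatenate([[v0], v])
    # linear-domain deficit: fully washed-out (zero) frames legitimately
    # contribute 1 to the integrand, so no frames are excluded here
    theta = float(_cumtrapz(t - t0, 1.0 - v / v0)[-1])
    horizon = duration_T - t0
    theta = float(np.clip(theta, 0.0, horizon))
    return WashoutIndex(theta=theta, duration_T=float(duration_T), washout_start=seg.washout_start)


def detect_reference_region(
    data: np.ndarray,
    frame_starts: np.ndarray,
    frame_ends: np.ndarray,
    seg: PhaseSegmentation,
    theta_threshold: float = DEFAULT_THETA_THRESHOLD_S,
    duration_T: float = DEFAULT_DURATION_T_S,
    mask: np.ndarray | None = None,
    min_cluster_size: int = 0,
) -> ReferenceCandidate:
    """Threshold the voxelwise Θ map to propose a reference region.

    Computes Θ over [seg.washout_start, duration_T] for every voxel (within
    ``mask`` if given) and returns the voxels with Θ > ``theta_threshold``.
    ``min_cluster_size`` > 0 drops candidates smaller than that many voxels
    (6-connectivity); default keeps the pure threshold.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, frames)")
    starts = np.asarray(frame_starts, dtype=float)
    ends = np.asarray(frame_ends, dtype=float)
    mids = (starts + ends) / 2.0
    if data.shape[3] != len(mids):
        raise ValueError("frame schedule length must match the image's 4th axis")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    theta_map = np.full(data.shape[:3], np.nan, dtype=float)
    durs = ends - starts
    for ix, iy, iz in np.argwhere(mask):
        vox = TimeActivityCurve(mids, durs, data[ix, iy, iz])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wi = washout_index(vox, seg, duration_T=duration_T)
            theta_map[ix, iy, iz] = wi.theta
        except (DegenerateSignalError, ValueError):
            continue
    with np.errstate(invalid="ignore"):
        cand = theta_map > theta_threshold
    if min_cluster_size > 0 and np.any(cand):
        from scipy import ndimage

        labeled, n = ndimage.label(cand)
        for lab in range(1, n + 1):
            if np.count_nonzero(labeled == lab) < min_cluster_size:
                cand[labeled == lab] = False
    count = int(np.count_nonzero(cand))
    if count == 0:
        warnings.warn("no voxels exceed the Θ threshold; empty candidate", stacklevel=2)
        mean_theta = float("nan")
    else:
        mean_theta = float(np.mean(theta_map[cand]))
    return ReferenceCandidate(
        mask=cand,
        theta_threshold=float(theta_threshold),
        voxel_count=count,
        mean_theta=mean_theta,
        theta_map=theta_map,
    )
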