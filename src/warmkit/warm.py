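"""Washout allometric reference method (WARM).

BP_ND of a rapidly cleared tracer is estimated purely from the washout
phase: after the bolus has left the circulation, each region decays
mono-exponentially, ln(m*(t)/m*(t0)) = -k2a t for a binding region and
-k2ND t for the reference.  With R1 = m*(t0)/m*ND(t0) the distribution
volume ratio is DVR = R1 k2ND / k2a, i.e. BP_ND = R1 k2ND/k2a - 1.

Two estimators are provided:

* the *allometric* (log–log) form — the reference log-fraction is regressed
  through the origin on the ROI log-fraction; the slope times R1 is DVR;
* the *operational* (integral) form —

      BP_ND(T) = [m*(t0) ∫_0^T ln(m*ND/m*ND(t0)) dt]
               / [m*ND(t0) ∫_0^T ln(m*/m*(t0)) dt] - 1

  whose integration strongly suppresses noise; the full BP_ND(T)
  trajectory over truncation times T is returned so convergence can be
  inspected.

Both are invariant under common rescaling of the two curves, and on
noiseless mono-exponential input they agree with the closed form exactly
(trapezoids are exact for the linear log-signals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSignalError, InsufficientDataError
from .tac import PhaseSegmentation, TimeActivityCurve, WashoutCurve, to_washout_curve

__all__ = [
    "KineticParameters",
    "WarmResult",
    "warm_bp_operational",
    "warm_bp_pointwise",
    "warm_bp_allometric",
    "warm_k2a",
    "warm_parametric_map",
]


@dataclass
class KineticParameters:
    """Container for one-tissue reference-model parameters.

    Rates are per minute; K1/K1ND in any consistent clearance unit.
    Cross-field identities (DVR = 1 + BP_ND, k2 = R1 k2ND, V_T >= V_ND)
    are validated when both sides are present.
    """

    k1: float | None = None
    k1nd: float | None = None
    k2: float | None = None
    k2a: float | None = None
    k2nd: float | None = None
    r1: float | None = None
    bp_nd: float | None = None
    dvr: float | None = None
    v_t: float | None = None
    v_nd: float | None = None

    def __post_init__(self):
        if self.dvr is not None and self.bp_nd is not None:
            if abs(self.dvr - (1.0 + self.bp_nd)) > 1e-9 * max(1.0, abs(self.dvr)):
                raise ValueError("DVR must equal 1 + BP_ND")
        if self.k2 is not None and self.r1 is not None and self.k2nd is not None:
            if abs(self.k2 - self.r1 * self.k2nd) > 1e-9 * max(1.0, abs(self.k2)):
                raise ValueError("k2 must equal R1 * k2ND")
        if self.v_t is not None and self.v_nd is not None and self.v_t < self.v_nd - 1e-12:
            raise ValueError("V_T must be >= V_ND")


@dataclass(frozen=True)
class WarmResult:
    """Outcome of a WARM fit: the converged BP_ND plus its trajectory."""

    bp_nd: float
    dvr: float
    r1_used: float
    trajectory_times: np.ndarray       # truncation times T (s from washout start)
    bp_trajectory: np.ndarray          # BP_ND(T) at each T
    n_excluded_frames: int = 0

    def __post_init__(self):
        if abs(self.dvr - (1.0 + self.bp_nd)) > 1e-9 * max(1.0, abs(self.dvr)):
            raise ValueError("dvr must equal 1 + bp_nd")
        if len(self.bp_trajectory) and not np.isclose(
            self.bp_trajectory[-1], self.bp_nd, rtol=1e-12, atol=1e-12, equal_nan=True
        ):
            raise ValueError("trajectory must end at bp_nd")


def _common_grid(roi: WashoutCurve, ref: WashoutCurve) -> tuple:
    """Shared washout grid: union of times on the overlapping interval,
    log-fractions linearly interpolated (logs taken before interpolation)."""
    t_end = min(roi.times_from_t0[-1], ref.times_from_t0[-1])
    t = np.union1d(roi.times_from_t0, ref.times_from_t0)
    t = t[t <= t_end]
    log_roi = np.interp(t, roi.times_from_t0, roi.log_fraction)
    log_ref = np.interp(t, ref.times_from_t0, ref.log_fraction)
    return t, log_roi, log_ref


def _cumtrapz(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.diff(t) * (y[:-1] + y[1:]) / 2.0)])


def warm_bp_operational(
    roi: WashoutCurve, ref: WashoutCurve, r1: float | None = None
) -> WarmResult:
    """BP_ND by the integral operational form.

    ``r1`` defaults to the initial-value ratio m*(t0)/m*ND(t0); supply a
    value (e.g. from a flow scan or the peak-ratio estimate) to override.
    The trajectory holds BP_ND(T) at every shared washout time after the
    origin; ``bp_nd`` is its final element.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 usable shared frames.
    DegenerateSignalError
        Flat ROI curve (zero denominator integral): "no washout signal".
    """
    t, log_roi, log_ref = _common_grid(roi, ref)
    if len(t) < 3:
        raise InsufficientDataError("fewer than 3 usable shared washout frames")
    if r1 is None:
        r1 = roi.initial_value / ref.initial_value
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    num = _cumtrapz(t, log_ref)   # ∫ ln(m*ND/m*ND(0)) dt
    den = _cumtrapz(t, log_roi)   # ∫ ln(m*/m*(0)) dt
    if den[-1] == 0.0:
        raise DegenerateSignalError("no washout signal: flat ROI curve")
    with np.errstate(divide="ignore", invalid="ignore"):
        traj = r1 * num[1:] / den[1:] - 1.0
    bp = float(traj[-1])
    return WarmResult(
        bp_nd=bp,
        dvr=1.0 + bp,
        r1_used=float(r1),
        trajectory_times=t[1:],
        bp_trajectory=traj,
        n_excluded_frames=roi.n_excluded + ref.n_excluded,
    )


def warm_bp_pointwise(
    roi: WashoutCurve, ref: WashoutCurve, r1: float | None = None
) -> WarmResult:
    """BP_ND from the un-integrated log-ratio at each washout time.

    DVR(T) = R1 ln(m*ND(T)/m*ND(0)) / ln(m*(T)/m*(0)) pointwise — the
    direct (noisier) counterpart the integral form stabilizes; exposed for
    variance comparisons against :func:`warm_bp_operational`.
    """
    t, log_roi, log_ref = _common_grid(roi, ref)
    if len(t) < 2:
        raise InsufficientDataError("fewer than 2 usable shared washout frames")
    if r1 is None:
        r1 = roi.initial_value / ref.initial_value
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    if np.all(log_roi[1:] == 0.0):
        raise DegenerateSignalError("no washout signal: flat ROI curve")
    with np.errstate(divide="ignore", invalid="ignore"):
        traj = r1 * log_ref[1:] / log_roi[1:] - 1.0
    bp = float(traj[-1])
    return WarmResult(
        bp_nd=bp,
        dvr=1.0 + bp,
        r1_used=float(r1),
        trajectory_times=t[1:],
        bp_trajectory=traj,
        n_excluded_frames=roi.n_excluded + ref.n_excluded,
    )


def warm_bp_allometric(roi: WashoutCurve, ref: WashoutCurve, r1: float) -> KineticParameters:
    """BP_ND by allometric log–log linearization.

    Fits the through-origin least-squares slope s of the reference
    log-fraction against the ROI log-fraction; DVR = s r1 and
    BP_ND = DVR - 1.  ``r1`` must be supplied (peak ratio, initial-value
    ratio, or an external flow estimate).
    """
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    t, log_roi, log_ref = _common_grid(roi, ref)
    if len(t) < 3:
        raise InsufficientDataError("fewer than 3 usable shared washout frames")
    sxx = float(np.dot(log_roi, log_roi))
    if sxx == 0.0:
        raise DegenerateSignalError("degenerate regressor: flat ROI curve")
    slope = float(np.dot(log_roi, log_ref)) / sxx
    dvr = slope * r1
    return KineticParameters(r1=r1, dvr=dvr, bp_nd=dvr - 1.0)


def warm_k2a(curve: WashoutCurve) -> float:
    """Apparent washout rate (per minute) from ln(fraction) = -k2a t.

    Through-origin least-squares slope of the log remaining fraction
    against time; returns 0.0 for a non-decreasing curve.
    """
    if len(curve) < 2:
        raise InsufficientDataError("need at least 2 positive washout frames")
    t_min = curve.times_from_t0 / 60.0
    logf = curve.log_fraction
    stt = float(np.dot(t_min, t_min))
    if stt == 0.0:
        raise DegenerateSignalError("washout curve has no time extent")
    k = -float(np.dot(t_min, logf)) / stt
    return max(k, 0.0)


def warm_parametric_map(
    data: np.ndarray,
    frame_starts: np.ndarray,
    frame_ends: np.ndarray,
    ref_tac: TimeActivityCurve,
    seg: PhaseSegmentation,
    mask: np.ndarray | None = None,
    r1_map: np.ndarray | None = None,
) -> tuple:
    """Voxelwise BP_ND map from the operational equation.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, n_frames)
        Dynamic image.
    frame_starts, frame_ends : array-like, seconds
        Frame schedule; must match ``ref_tac``'s frames.
    ref_tac : TimeActivityCurve
        Reference-region curve on the same schedule.
    seg : PhaseSegmentation
        Phase split applied to every voxel and to the reference.
    mask : ndarray of bool, optional
        Voxels to process (default: all).
    r1_map : ndarray, optional
        Per-voxel R1 override; default is the initial-value ratio.

    Returns
    -------
    (bp_map, n_failed) : voxels failing the estimator preconditions are NaN
    and counted.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, frames)")
    starts = np.asarray(frame_starts, dtype=float)
    ends = np.asarray(frame_ends, dtype=float)
    if data.shape[3] != len(starts) or len(starts) != len(ends):
        raise ValueError("frame schedule length must match the image's 4th axis")
    mids = (starts + ends) / 2.0
    if len(ref_tac) != len(mids) or not np.allclose(ref_tac.frame_mid_times, mids):
        raise ValueError("reference TAC frame schedule does not match the image")
    ref_wc = to_washout_curve(ref_tac, seg)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    bp_map = np.full(data.shape[:3], np.nan, dtype=float)
    n_failed = 0
    durs = ends - starts
    idx = np.argwhere(mask)
    for ix, iy, iz in idx:
        vox = TimeActivityCurve(mids, durs, data[ix, iy, iz])
        try:
            wc = to_washout_curve(vox, seg)
            r1 = None if r1_map is None else float(r1_map[ix, iy, iz])
            res = warm_bp_operational(wc, ref_wc, r1=r1)
            bp_map[ix, iy, iz] = res.bp_nd
        except (DegenerateSignalError, InsufficientDataError, ValueError):
            n_failed += 1
    return bp_map, n_failed
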