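"""Time–activity curves and the three-phase split of a washout-tracer signal.

A dynamic record of a rapidly cleared tracer such as [11C]PIB decomposes into
an arterial spike (first ~2 min), a peak-uptake phase (~2–10 min) and a long
washout tail.  The types here carry a regional/voxel time–activity curve
(TAC), the phase boundaries, and the normalized "remaining fraction" curve
m*(t)/m*(t0) that the washout estimators consume.

Conventions: all times are seconds; every computation uses frame mid-times;
integrals downstream are trapezoidal over mid-times.  Inputs are assumed
decay-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DegenerateSignalError, InsufficientDataError, QualityWarning

__all__ = [
    "TimeActivityCurve",
    "ArterialInput",
    "PhaseSegmentation",
    "WashoutCurve",
    "split_phases",
    "to_washout_curve",
    "window_auc",
]

#: fraction of washout frames that may be dropped (non-positive values)
#: before a quality warning is raised
MAX_EXCLUDED_FRACTION = 0.25


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class TimeActivityCurve:
    """Radioactivity concentration vs. frame mid-time for one region or voxel.

    Parameters
    ----------
    frame_mid_times : array-like
        Frame mid-times in seconds, strictly increasing.
    frame_durations : array-like
        Frame durations in seconds, all positive.
    values : array-like
        Activity concentration per frame (any consistent unit, e.g. Bq/mL).
    label : str
        Free-text region/voxel label.
    """

    frame_mid_times: np.ndarray
    frame_durations: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = _as_float_array(self.frame_mid_times, "frame_mid_times")
        d = _as_float_array(self.frame_durations, "frame_durations")
        v = _as_float_array(self.values, "values")
        if not (len(t) == len(d) == len(v)):
            raise ValueError("frame_mid_times, frame_durations and values must have equal length")
        if len(t) == 0:
            raise ValueError("empty time-activity curve")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame_mid_times must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("frame_durations must be positive")
        object.__setattr__(self, "frame_mid_times", t)
        object.__setattr__(self, "frame_durations", d)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_frames(cls, frame_start_s, frame_end_s, values, label: str = "") -> "TimeActivityCurve":
        """Build from frame start/end times; mid-time is their average."""
        start = _as_float_array(frame_start_s, "frame_start_s")
        end = _as_float_array(frame_end_s, "frame_end_s")
        if np.any(end <= start):
            raise ValueError("frame_end_s must exceed frame_start_s")
        if np.any(start[1:] < end[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        return cls((start + end) / 2.0, end - start, values, label)

    @property
    def frame_starts(self) -> np.ndarray:
        return self.frame_mid_times - self.frame_durations / 2.0

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_mid_times + self.frame_durations / 2.0

    def __len__(self) -> int:
        return len(self.values)

    def truncated(self, end_time_s: float) -> "TimeActivityCurve":
        """Frames with mid-time <= ``end_time_s`` (shortened tomography)."""
        keep = self.frame_mid_times <= end_time_s
        if not np.any(keep):
            raise InsufficientDataError("no frames before requested end time")
        return replace(
            self,
            frame_mid_times=self.frame_mid_times[keep],
            frame_durations=self.frame_durations[keep],
            values=self.values[keep],
        )

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return replace(self, values=self.values * factor)


@dataclass(frozen=True)
class ArterialInput:
    """Arterial whole-blood/plasma concentration c_a(t) driving tissue uptake."""

    sample_times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.sample_times, "sample_times")
        c = _as_float_array(self.concentrations, "concentrations")
        if len(t) != len(c):
            raise ValueError("sample_times and concentrations must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return len(self.sample_times)


@dataclass(frozen=True)
class PhaseSegmentation:
    """Arterial / peak-uptake / washout partition of a TAC.

    ``peak_time`` is the frame mid-time of the maximum value inside
    ``peak_window``; ``washout_start`` (t0) defaults to the peak, and
    ``washout_end`` (T) bounds the analysis.
    """

    arterial_end: float
    peak_window: tuple
    peak_time: float
    peak_value: float
    washout_start: float
    washout_end: float

    def __post_init__(self):
        lo, hi = self.peak_window
        if not (self.arterial_end <= lo < hi):
            raise ValueError("need arterial_end <= peak_window.start < peak_window.end")
        if not (lo <= self.peak_time <= hi):
            raise ValueError("peak_time must lie inside the peak window")
        if self.washout_start < self.arterial_end:
            raise ValueError("washout_start must not precede arterial_end")
        if self.washout_end <= self.washout_start:
            raise ValueError("washout_end must exceed washout_start")


@dataclass(frozen=True)
class WashoutCurve:
    """Remaining-fraction curve m*(t)/m*(t0) on the washout phase.

    ``times_from_t0`` starts at 0 where the fraction is exactly 1;
    ``initial_value`` is m*(t0).  Frames whose value was non-positive are
    excluded (never clipped) and counted in ``n_excluded``.
    """

    times_from_t0: np.ndarray
    remaining_fraction: np.ndarray
    initial_value: float
    n_excluded: int = 0
    label: str = ""

    def __post_init__(self):
        t = _as_float_array(self.times_from_t0, "times_from_t0")
        f = _as_float_array(self.remaining_fraction, "remaining_fraction")
        if len(t) != len(f):
            raise ValueError("times and fractions must have equal length")
        if len(t) == 0:
            raise DegenerateSignalError("empty washout curve")
        if t[0] != 0.0 or abs(f[0] - 1.0) > 1e-12:
            raise ValueError("washout curve must start at (t=0, fraction=1)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times_from_t0 must be strictly increasing")
        if np.any(f <= 0):
            raise ValueError("remaining fractions must be strictly positive")
        if self.initial_value <= 0:
            raise DegenerateSignalError("non-positive washout origin")
        object.__setattr__(self, "times_from_t0", t)
        object.__setattr__(self, "remaining_fraction", f)

    def __len__(self) -> int:
        return len(self.times_from_t0)

    @property
    def values(self) -> np.ndarray:
        """Absolute activity values of the retained frames."""
        return self.remaining_fraction * self.initial_value

    @property
    def log_fraction(self) -> np.ndarray:
        """ln(m*(t)/m*(t0)); zero at the origin by construction."""
        return np.log(self.remaining_fraction)

    def truncated(self, end_time_from_t0: float) -> "WashoutCurve":
        keep = self.times_from_t0 <= end_time_from_t0
        if np.count_nonzero(keep) < 2:
            raise InsufficientDataError("fewer than 2 frames before requested end time")
        return replace(
            self,
            times_from_t0=self.times_from_t0[keep],
            remaining_fraction=self.remaining_fraction[keep],
        )


def split_phases(
    tac: TimeActivityCurve,
    arterial_end: float = 120.0,
    peak_window: tuple = (120.0, 600.0),
    washout_end: float = 3600.0,
) -> PhaseSegmentation:
    """Split a TAC into arterial, peak-uptake and washout phases.

    The peak is the maximum value among frames whose mid-time lies in
    ``peak_window`` (earliest frame on ties); the washout phase runs from
    the peak to ``washout_end``.

    Raises
    ------
    InsufficientDataError
        If the TAC does not cover the peak window.
    DegenerateSignalError
        If the TAC is identically zero.
    """
    lo, hi = peak_window
    if tac.frame_mid_times[-1] < lo:
        raise InsufficientDataError("insufficient duration: TAC ends before the peak window")
    if np.all(tac.values == 0):
        raise DegenerateSignalError("degenerate signal: all-zero TAC")
    in_window = (tac.frame_mid_times >= lo) & (tac.frame_mid_times <= hi)
    if not np.any(in_window):
        raise InsufficientDataError("insufficient duration: no frames inside the peak window")
    idx = np.flatnonzero(in_window)
    # argmax returns the first maximum -> earliest frame wins ties
    peak_idx = idx[int(np.argmax(tac.values[idx]))]
    peak_time = float(tac.frame_mid_times[peak_idx])
    peak_value = float(tac.values[peak_idx])
    return PhaseSegmentation(
        arterial_end=arterial_end,
        peak_window=(lo, hi),
        peak_time=peak_time,
        peak_value=peak_value,
        washout_start=peak_time,
        washout_end=washout_end,
    )


def window_auc(tac: TimeActivityCurve, start: float, end: float) -> float:
    """Trapezoidal AUC of a TAC over ``[start, end]`` seconds.

    The curve must cover the window up to its frame extents; inside the
    first/last half-frame the edge value is held constant.
    """
    if start >= end:
        raise ValueError("window start must precede its end")
    t, v = tac.frame_mid_times, tac.values
    if tac.frame_starts[0] > start + 1e-9 or tac.frame_ends[-1] < end - 1e-9:
        raise InsufficientDataError("curve does not cover the integration window")
    inner = (t > start) & (t < end)
    tt = np.concatenate([[start], t[inner], [end]])
    vv = np.concatenate([[np.interp(start, t, v)], v[inner], [np.interp(end, t, v)]])
    return float(np.trapezoid(vv, tt))


def to_washout_curve(tac: TimeActivityCurve, seg: PhaseSegmentation) -> WashoutCurve:
    """Normalize the washout phase of ``tac`` to its value at t0.

    Keeps frames with mid-time in ``[washout_start, washout_end]``, divides
    by the value at ``washout_start`` and drops (counting) any non-positive
    frames.  More than 25% exclusions raises a :class:`QualityWarning`.
    """
    t = tac.frame_mid_times
    keep = (t >= seg.washout_start) & (t <= seg.washout_end)
    if not np.any(keep):
        raise InsufficientDataError("no frames inside the washout phase")
    times = t[keep]
    vals = tac.values[keep]
    # value at t0: the first retained frame must sit at washout_start
    if abs(times[0] - seg.washout_start) > 1e-9:
        # t0 between frames: interpolate the origin value
        v0 = float(np.interp(seg.washout_start, t, tac.values))
        times = np.concatenate([[seg.washout_start], times])
        vals = np.concatenate([[v0], vals])
    v0 = vals[0]
    if v0 <= 0:
        raise DegenerateSignalError("non-positive washout origin")
    positive = vals > 0
    n_excluded = int(np.count_nonzero(~positive))
    if n_excluded > 0 and n_excluded / len(vals) > MAX_EXCLUDED_FRACTION:
        warnings.warn(
            f"{n_excluded}/{len(vals)} washout frames non-positive and excluded",
            QualityWarning,
            stacklevel=2,
        )
    times = times[positive]
    vals = vals[positive]
    return WashoutCurve(
        times_from_t0=times - seg.washout_start,
        remaining_fraction=vals / v0,
        initial_value=float(v0),
        n_excluded=n_excluded,
        label=tac.label,
    )
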