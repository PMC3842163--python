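"""Wash-in-based flow estimation and the [15O]water CBF fit.

During the brief uptake phase (before the peak, ~2–10 min) no tracer has
left the tissue, so the peak signal is proportional to delivery.  This
yields:

* ``r1_from_peaks`` — the relative delivery R1 as the ratio of peak values
  m(Δtp)/m_ND(Δtp_ref);
* the Renkin–Crone link between delivery and flow, K1 = CBF (1 - e^(-PS/CBF)),
  with extraction fraction E = 1 - e^(-PS/CBF); the peak-ratio estimate
  approaches the true flow ratio when extraction fractions match
  (high PS, or CBF close to the reference's);
* ``surrogate_k1`` — a delay-, weight- and dose-normalized K1 magnitude,
  (m(Δtp)/Δtp) · Δtp_ref · weight/dose, which a site-specific constant
  K_site converts into a surrogate CBF in mL·hg⁻¹·min⁻¹;
* ``cbf_water_blomquist`` — absolute CBF as the unidirectional [15O]water
  clearance K1 from the linearized one-tissue relation
  m(T) = K1 ∫ c_a dt - k2 ∫ m dt, solved by Lawson–Hanson non-negative
  least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .exceptions import DegenerateSignalError, WarmkitError
from .tac import ArterialInput, PhaseSegmentation, TimeActivityCurve

__all__ = [
    "FlowEstimate",
    "WaterCbfResult",
    "r1_from_peaks",
    "extraction_fraction",
    "predicted_r1pib",
    "surrogate_k1",
    "calibrate_k_site",
    "cbf_water_blomquist",
]


@dataclass
class FlowEstimate:
    """Flow-related quantities for one region or voxel."""

    r1_pib: float | None = None
    extraction_e: float | None = None
    extraction_end: float | None = None
    ps: float | None = None
    k1_surrogate: float | None = None
    cbf_surrogate: float | None = None
    k_site: float | None = None

    def __post_init__(self):
        for name in ("extraction_e", "extraction_end"):
            e = getattr(self, name)
            if e is not None and not (0.0 < e <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if (
            self.cbf_surrogate is not None
            and self.k_site is not None
            and self.k1_surrogate is not None
        ):
            if not math.isclose(self.cbf_surrogate, self.k_site * self.k1_surrogate,
                                rel_tol=1e-9):
                raise ValueError("cbf_surrogate must equal k_site * k1_surrogate")


@dataclass(frozen=True)
class WaterCbfResult:
    """Non-negative (K1, k2) from the linearized water model; K1 is CBF."""

    k1_water: float
    k2_water: float
    residual_norm: float

    def __post_init__(self):
        if self.k1_water < 0 or self.k2_water < 0:
            raise ValueError("water-fit parameters must be non-negative")


def r1_from_peaks(roi_seg: PhaseSegmentation, ref_seg: PhaseSegmentation) -> float:
    """R1 estimate: ROI peak value / reference peak value."""
    if roi_seg.peak_value <= 0 or ref_seg.peak_value <= 0:
        raise DegenerateSignalError("non-positive peak value")
    return roi_seg.peak_value / ref_seg.peak_value


def extraction_fraction(ps: float, cbf: float) -> float:
    """Renkin–Crone extraction E = 1 - e^(-PS/CBF)."""
    if cbf <= 0:
        raise WarmkitError("CBF must be positive")
    if ps < 0:
        raise WarmkitError("PS must be non-negative")
    return -math.expm1(-ps / cbf)


def predicted_r1pib(r1: float, e: float, e_nd: float) -> float:
    """Delivery ratio implied by a flow ratio and the two extractions:
    R1^PIB = R1 · E / E_ND."""
    if not (0.0 < e <= 1.0) or not (0.0 <= e_nd <= 1.0):
        raise WarmkitError("extraction fractions must lie in (0, 1]")
    if e_nd == 0.0:
        raise WarmkitError("reference extraction must be positive")
    return r1 * e / e_nd


def surrogate_k1(
    seg: PhaseSegmentation,
    ref_peak_time: float,
    weight_kg: float,
    dose_mbq: float,
) -> float:
    """Delay-normalized K1 magnitude: (m(Δtp)/Δtp) · Δtp_ref · weight/dose."""
    if weight_kg <= 0 or dose_mbq <= 0:
        raise WarmkitError("weight and dose must be positive")
    if seg.peak_time <= 0 or ref_peak_time <= 0:
        raise WarmkitError("peak times must be positive")
    if seg.peak_value <= 0:
        raise DegenerateSignalError("non-positive peak value")
    return (seg.peak_value / seg.peak_time) * ref_peak_time * weight_kg / dose_mbq


def calibrate_k_site(cortex_k1_estimates, cortex_cbf_values) -> float:
    """Site calibration constant from healthy-control cortex data.

    K_site = mean(CBF) / mean(K1 surrogate); the surrogate CBF of any
    region is then K_site times its K1 surrogate.
    """
    k1 = np.asarray(cortex_k1_estimates, dtype=float)
    cbf = np.asarray(cortex_cbf_values, dtype=float)
    if k1.size == 0 or cbf.size == 0:
        raise WarmkitError("calibration lists must be non-empty")
    if k1.size != cbf.size:
        raise WarmkitError("calibration lists must have equal length")
    if np.any(k1 <= 0) or np.any(cbf <= 0):
        raise WarmkitError("calibration values must be positive")
    return float(np.mean(cbf) / np.mean(k1))


def calibrate_k_site_regression(cortex_k1_estimates, cortex_cbf_values) -> float:
    """Alternative: through-origin regression of CBF on the K1 surrogate."""
    k1 = np.asarray(cortex_k1_estimates, dtype=float)
    cbf = np.asarray(cortex_cbf_values, dtype=float)
    if k1.size == 0 or k1.size != cbf.size:
        raise WarmkitError("calibration lists must be non-empty and of equal length")
    denom = float(np.dot(k1, k1))
    if denom == 0.0:
        raise WarmkitError("degenerate calibration data")
    return float(np.dot(k1, cbf)) / denom


def cbf_water_blomquist(
    tissue: TimeActivityCurve, input_function: ArterialInput
) -> WaterCbfResult:
    """CBF as [15O]water clearance from the linearized one-tissue model.

    Builds the design m(T_i) = K1 ∫_0^{T_i} c_a dt - k2 ∫_0^{T_i} m dt at
    the tissue frame mid-times (cumulative trapezoids; the tissue curve is
    anchored at m(0) = 0, the input interpolated onto the tissue grid) and
    solves for (K1, k2) >= 0 by Lawson–Hanson NNLS.  K1 is in
    mL·hg⁻¹·min⁻¹ when c_a and m share units and k2 is per minute.
    """
    tt = tissue.frame_mid_times
    tv = tissue.values
    at = input_function.sample_times
    if at[0] > 0.0 or at[-1] < tt[-1] - 1e-9:
        raise WarmkitError("input function must cover [0, end of tissue curve]")
    # work in minutes so K1 and k2 come out per minute
    grid = np.union1d(np.concatenate([[0.0], tt]), at[at <= tt[-1] + 1e-9]) / 60.0
    ca = np.interp(grid, at / 60.0, input_function.concentrations)
    m = np.interp(grid, np.concatenate([[0.0], tt]) / 60.0, np.concatenate([[0.0], tv]))
    cum_ca = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (ca[:-1] + ca[1:]) / 2.0)])
    cum_m = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (m[:-1] + m[1:]) / 2.0)])
    t_obs = tt / 60.0
    design = np.column_stack([
        np.interp(t_obs, grid, cum_ca),
        -np.interp(t_obs, grid, cum_m),
    ])
    if np.all(tv == 0.0):
        # no tissue signal: zero clearance, washout unidentifiable -> 0
        return WaterCbfResult(k1_water=0.0, k2_water=0.0, residual_norm=0.0)
    if np.linalg.matrix_rank(design) < 2:
        raise DegenerateSignalError("rank-deficient design in the water fit")
    coef, resid = nnls(design, tv)
    return WaterCbfResult(k1_water=float(coef[0]), k2_water=float(coef[1]),
                          residual_norm=float(resid))
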