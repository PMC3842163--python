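# Methods

## Model and assumptions

All estimators operate on the one-tissue reference model. A region of
interest (ROI) and a reference region exchange tracer with arterial blood
`c_a(t)`:

```
dm*(t)/dt   = K1   c_a(t) - k2a  m*(t)
dm*ND(t)/dt = K1ND c_a(t) - k2ND m*ND(t)
```

The WARM chain assumes, additionally, that the arterial supply is
effectively gone after a brief wash-in, so that from the washout origin t0
onward each region decays mono-exponentially. Under that condition

* `k2a = k2 / (1 + BP_ND)` — binding slows the apparent washout;
* `k2  = R1 · k2ND` — delivery scales the non-displaceable washout
  (equal V_ND everywhere);
* `DVR = R1 · k2ND / k2a`, `BP_ND = DVR - 1`.

Two identities about the operational (integral) estimator follow and are
exploited by the tests: on noiseless mono-exponential input the log
remaining-fractions are linear in time, so the trapezoidal integrals are
exact and `BP_ND(T)` is constant in T; and multiplying both curves by one
positive constant leaves the estimate unchanged because the initial-value
prefactor cancels the normalization.

The decision to read `k2a = k2/(1+BP_ND)` (rather than its reciprocal
form, which appears inconsistently in parts of the published derivation)
is forced by requiring the identities above to be mutually consistent:
only this orientation makes `V_T = K1(1+BP)/k2`, `k2 = R1 k2ND` and
`DVR = R1 k2ND/k2a` one algebraic system.

## Phase segmentation

The signal of a rapidly cleared tracer splits into an arterial spike
(default first 120 s), a peak-uptake window (default 120–600 s) and the
washout. The peak is the frame mid-time of the maximum value inside the
window, ties resolved to the earliest frame (deterministic, and the safest
choice for the downstream pure-washout assumption). The washout origin
defaults to the peak itself — by the peak, net uptake has ceased — with a
configurable fixed override (`fixed_washout_start_s`, e.g. 120 s) for
protocols that prefer a fixed t0.

Non-positive frame values inside the washout cannot enter the log domain;
they are excluded (never clipped, which would bias the log integrals) and
counted, and an exclusion fraction above 25% raises a quality warning.
The washout index Θ is the one place this rule does not apply: Θ is a
linear-domain integral, `Θ = ∫ (1 - m*(t)/m*(t0)) dt`, where a fully
washed-out (zero) frame legitimately contributes its whole duration to
the deficit, so Θ keeps all frames and only requires a positive origin.

## R1 sources

The operational estimator needs R1. Three sources are supported, in the
order a practitioner would prefer them:

1. an external estimate (e.g. from [¹⁵O]water), passed explicitly;
2. the uptake-peak ratio `m(Δtp)/m_ND(Δtp_ref)` — valid when extraction
   fractions match (high PS, or CBF near the reference's, per the
   Renkin–Crone relation `E = 1 - exp(-PS/CBF)`);
3. the initial-value ratio `m*(t0)/m*ND(t0)` at the washout origin — the
   default, and the form the integral estimator is written in.

On coupled-kinetics data the peak ratio carries a bias factor
`exp(-(k2a - k2ND)·δt)` where δt is the lag between the bolus and the
tissue peak; it vanishes for a rapidly cleared bolus sampled with fine
early frames. The initial-value ratio carries the analogous factor with
δt = t0 − (bolus time), which grows with t0 — so for coupled data the
peak-ratio source combined with a later washout origin is the accurate
pairing, and is what the cross-method consistency check uses.

## Noise model and the synthetic generators

All generators add zero-mean Gaussian noise with standard deviation
proportional to the instantaneous noiseless value (default fraction 0.20
for the canonical washout pair), independent across frames and voxels.
This keeps relative SNR constant along the curve. It does **not** emulate
frame-duration/decay weighting, detector covariance, or reconstruction
correlations of real PET data; passing tests demonstrate estimator
correctness under proportional noise, not performance on scanner data.

The canonical simulated pair uses a reference rate of 0.92/min and a
binding-region rate of 0.98/min, interpreted as per-minute constants
(consistent with a 2–60 min analysis window), amplitude 100 at the
washout origin, 5-s frames over 10 min. With these rates the signal is
~e⁻⁹ of its origin by 10 min, so longer horizons add no information.

The coupled simulator integrates the one-tissue equations with an exact
per-step exponential-convolution update for piecewise-linear input
(vectorized as a first-order IIR filter). This is exact for the sampled
input — better than a fixed-step Runge–Kutta scheme at the same grid —
and reproducible to the bit. Frame values are interval averages computed
from the fine-grid cumulative trapezoid. The gamma-variate bolus
`c(t) = scale·(t/tp)^shape·e^{shape(1-t/tp)}` peaks exactly at tp.

The 4D phantom assigns each voxel its region's mono-exponential washout
with independent proportional noise. Region amplitudes are defined **at
the washout origin** (the first frame mid-time): the voxel-to-reference
initial-value ratio then equals the region's R1 exactly, which makes the
closed form `BP = R1 k2ND/k2a - 1` hold for the parametric map without
simulating a wash-in phase. The phantom has no resolution, attenuation,
scatter or partial-volume effects.

## Estimator implementation notes

* **Quadrature/grid** — log remaining-fractions are computed per curve
  (log before interpolation), linearly interpolated onto the union of the
  two washout grids restricted to their common interval, and integrated
  by cumulative trapezoid. The BP trajectory is sampled at every shared
  washout time after the origin; at least 3 usable shared frames are
  required.
* **Allometric fit** — through-origin least squares of reference
  log-fraction on ROI log-fraction; the exponent times R1 is DVR.
* **`warm_k2a`** — through-origin slope of ln(fraction) vs time; a
  non-decreasing curve returns 0 with rate semantics rather than a
  negative rate.
* **SRTM** — basis-function search: for each k2a on a fixed 64-point
  log-spaced grid in [10⁻³, 2] min⁻¹, the two linear coefficients
  (R1, k2 − R1·k2a) are profiled out by least squares; the best cell is
  refined by bounded scalar minimization. The fixed grid makes the fit
  deterministic. The measured reference enters as frame averages, so the
  model reconstructs a fine-grid curve whose frame averages match the
  data (a linearly convergent fixed-point correction, contraction ≈ 0.45,
  iterated to 10⁻¹² relative) before convolving. Residuals are unweighted
  by default; frame-duration weights are an option. Non-convergence is
  flagged in the result, not raised. Note the model is structurally
  unidentifiable in k2 exactly on the surface `R1 = 1 + BP_ND`
  (`k2a = k2ND`, where ROI ≡ R1·reference); R1 and BP_ND remain
  identified there.
* **SUVR / flow-devolved BP** — trapezoidal AUC over the 2400–3600 s
  window; coverage is judged against frame extents, with the edge value
  held constant inside the outermost half-frames (frame mid-times alone
  would reject a 60-min scan whose final frame mid falls at 3510 s).
* **Water fit** — the linearized one-tissue relation
  `m(T) = K1∫c_a - k2∫m` is assembled at the tissue frame mid-times from
  cumulative trapezoids (tissue anchored at m(0)=0, input interpolated
  onto the union grid) and solved by Lawson–Hanson NNLS, so the
  parameters can never be negative. An identically zero tissue curve
  returns (0, 0) rather than a rank error.
* **Θ detection** — pure thresholding of the voxelwise Θ map (default
  Θ > 1660 s over a 1890 s horizon); an optional minimum-cluster-size
  filter (6-connectivity) is off by default so the detector stays
  faithful to the threshold image.
* **Missing values** — failed voxels in parametric maps are NaN and
  counted; sidecars record the counts and the full configuration.

The Θ formula itself is a reconstruction from its published properties —
units of time, bounded by the scan duration, approaching it for fast
unhindered washout — rather than a transcription of the original
Hypotime definition, which is specified in a separate publication; it
satisfies all three properties and the published selection behaviour,
but numerical identity with the original is not guaranteed.

## Variance behaviour of the integral estimator

Integration strongly suppresses the frame-noise contribution: at fixed
truncation time T the integral form has strictly smaller across-seed
variance than the pointwise log-ratio (measured ratio ≈ 0.74 at the
canonical rates and noise). As a function of T, however, two regimes
exist. The integral-noise part of the variance decays roughly as T⁻³,
but when R1 is estimated from the noisy initial values its variance
(~2·(noise fraction)² relative) is independent of T, so the total
variance *rises* toward that floor as the cancellation between the origin
noise inside and outside the integrals weakens (the cross-term scales as
2/(kT)). With R1 supplied independently, the variance of the truncation
profile falls monotonically — an order of magnitude from 20 to 60 min in
the measured configurations. Truncation-stability analyses in this
package therefore fix R1 when the question is integration smoothing.

## Problem sizes

Default test and acceptance runs use: 45-cell and 27-cell noiseless
parameter grids; 200 Monte-Carlo replicates for the noisy washout-pair
and SRTM experiments; a 4×4×2-voxel, 190-frame phantom for Θ detection
(5 replicates); 0.5-s sampling for Θ closed-form checks and 0.05-s
sampling for the water-fit forward simulations, where the comparison
tolerances are at the quadrature-resolution level. These sizes keep the
full suite around ten seconds while leaving Monte-Carlo standard errors
well below the tolerances being checked.

## Known limitations

* Single-exponential washout only; multi-compartment washout, plasma
  input modelling for the binding tracer, and partial-volume correction
  are out of scope.
* Inputs are assumed decay-corrected; no motion correction or frame
  re-binning beyond mid-time trapezoids.
* The SRTM Monte-Carlo contract treats the reference as the regression
  model's noise-free regressor (in practice a large-region mean). With
  heavy noise on the reference itself, any SRTM implementation is
  attenuation-biased (errors-in-variables), and this package makes no
  attempt to correct for that.
* The surrogate-CBF calibration constant K_site is site- and
  tomograph-specific and must come from user-supplied (or simulated)
  normal material; no value ships with the package. CO₂-tension
  correction of CBF is accepted as pre-corrected input only.
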