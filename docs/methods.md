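# Methods

This note documents the models implemented in `centrikit`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generators do and do not emulate.

## Observation volume and units

The confocal detection profile is a 3D Gaussian with lateral 1/e^2
radius `omega_xy`, axial radius `omega_z = AR * omega_xy`, and
effective volume `V_eff = pi^(3/2) * AR * omega_xy^3`.  The default
instrument geometry is `V_eff = 0.25 fl`, `AR = 5`, giving
`omega_xy = 0.208 um`.  Lengths are in um, times in seconds (minutes in
kinetics outputs), concentrations in nM, brightness in counts/s.  With
these units 1 fl = 1 um^3 and 1 nM = 0.6022 molecules/um^3.

## Photon-trace simulator (`centrikit.synth.traces`)

The forward measurement model is the standard one under which the FCS
fitting equations are exact: point emitters diffuse in a periodic box,
the detected intensity is the sum of per-fluorophore brightnesses
weighted by the Gaussian profile, and counts per detector bin are
Poisson draws of the integrated intensity plus a constant background.

* **Box geometry.** The box is periodic and anisotropic, half-widths
  `box_factor * (omega_xy, omega_xy, omega_z)` with `box_factor >= 5`
  (default 8).  An isotropic box of several axial radii on every side
  would hold ~10^5 molecules at the default occupancy and make the
  mandated multi-second protocols unaffordable; the anisotropic box
  keeps every boundary >= 5 beam radii from the focus, where the
  detection weight is < e^-50, so wrap-around is uncorrelated with the
  signal.  This is standard practice in FCS Brownian simulators.
* **Propagation.** Free diffusion uses per-axis Gaussian steps of
  s.d. `sqrt(2 D dt)`.  Anomalous subdiffusion (`alpha < 1`) uses
  fractional Brownian motion with Hurst index `alpha/2`, generated
  exactly by circulant embedding (power-of-two padded, batched
  single-precision FFTs); per-axis MSD is `2 D t^alpha`, the process
  whose ACF matches the fitted `(tau/tau_D)^alpha` form.
* **Dark states.** Triplet and blinking are independent two-state
  Markov chains per fluorophore, parameterized by stationary dark
  fraction and relaxation time, sampled by exponential dwell times and
  rasterized at bin starts.  Brightness is gated multiplicatively,
  matching the multiplicative dark-state factors in the fitted model.
  Resolving the 1-10-us triplet regime requires `dt_sim` of ~1 us;
  dark-state recovery tests therefore use short (sub-second) traces.
* **Oligomers.** Each of `n_subunits` subunits carries a mature
  fluorophore independently with probability `p_mature`; particles with
  zero mature subunits are still propagated (they carry no signal but
  keep the apparent-N statistics of the visible population correct).
* **Transits.** A "transit event" is a bright object crossing the
  focus laterally over a set duration — the minimal model of a
  centriole or yolk granule drifting through the spot, used to exercise
  the downstream rejection screens.
* **Numerics.** Positions are float32 (beam radius resolved to ~1e-5),
  the Gaussian exponent is clipped at 30 (weights < 1e-13 dropped), and
  the intensity is sampled at step starts.  A fused numba kernel is
  used for the free-diffusion and gated-Brownian cases; the vectorized
  numpy path is the reference implementation and handles fBm and path
  export.  All randomness flows from one SFC64 generator seeded by the
  config, so identical configs give bit-identical traces.

The simulator does not model optics (PSF aberration, pinhole, detector
afterpulsing), embryo-scale gradients, or cell-cycle biochemistry.

## Correlation (`centrikit.correlation`)

The multi-tau estimator evaluates `G(tau) = <dI dI_tau>/<I>^2` on a
quasi-logarithmic grid: `m_per_stage` (default 16) linear lags per
stage, trace coarsened 2x between stages, symmetric normalization
(separate left/right means per lag) to suppress finite-trace bias.  The
first stage is by construction identical to the direct O(n^2)
estimator; later stages agree within the coarsening error (< 2% RMS on
diffusion traces).

Per-embryo protocols are screened as follows: a segment is discarded if
its mean rate deviates > 50% from the embryo median or if its curve
fails to decay (mean G over the longest lag decade above 20% of the
initial amplitude); the embryo is dropped when fewer than 4 segments
survive.  The thresholds are declared package defaults — the original
rejection rule for "erratic" curves is not specified anywhere — chosen
to catch simulated transit events while passing clean segments.

Background correction: `N_corr = N (1 - b/r)^2`,
`CPM = (r - b)/N_corr`, with the background rate a user calibration
input (default 0).

## FCS fitting and model selection (`centrikit.fcsfit`)

Eight models (1 or 2 species x none/triplet/blink/triplet+blink) are
fitted by bounded trust-region least squares; `tau_T` in [1, 10] us,
`tau_B` in [10, 300] us, AR fixed at 5, lag range 0.4 ns to 200 ms
(3,000 ms configurable for slow species).  `BIC = n ln(RSS/n) +
k ln n` on the lag-domain residuals, unweighted by default with
optional per-lag weights; the residual scale is floored near machine
precision so that noise-free comparisons between nested models are
decided by the parameter penalty.  Two-species fits assume equal
brightness and share one alpha.

Model/alpha selection fits every candidate to the **segment-averaged**
curve of the calibration set and minimizes total BIC.  Selection on
individual segments was found to reward the 2-species model for
chasing per-segment noise; fitting the pooled mean curve — standard
FCS practice — removes that bias while leaving real structure
detectable.  Anomalous subdiffusion and two-component diffusion
produce nearly degenerate decays over a few decades of lag, so
recovering alpha on its 0.05 grid demands very clean curves.  At
desk-scale trace budgets (seconds of data, a handful of molecules in
the focus) the pooled correlation curve carries seed-dependent
occupancy wiggles of several percent at mid lags — enough to pull the
selected alpha one or two grid steps toward 1 or to let a two-species
model substitute.  The alpha-recovery validation therefore draws
calibration curves from the anomalous model itself at realistic
segment-scatter noise (selection then recovers alpha = 0.80 exactly),
while species-count and dark-state structure are validated end-to-end
on simulated traces.  In practice the per-protein alpha is likewise
calibrated once on dedicated high-quality curves and then frozen.

Curves whose initial amplitude is below three times the tail scatter
are flagged `amplitude_below_noise_floor` and excluded rather than
fitted — the regime handled by peak counting.

ROUT outlier removal re-implements the published algorithm sketch for
the constant model: IRLS location fit with Lorentzian weights, robust
scale from the 68.27th percentile of absolute residuals with n/(n-K)
correction, and a Benjamini-Hochberg FDR step at Q (default 1%) on
two-tailed t statistics.  Exact agreement with the commercial
implementation is not claimed; on clean Gaussian data the realized
false-flag rate is well below Q.

## PeCoS (`centrikit.pecos`)

Intervals (default 60 s) are smoothed with a moving average (default
1 ms), thresholded at `median + k * 1.4826 * MAD` (default k = 4), and
maximal super-threshold runs are counted.  Counting is scale-invariant
because the threshold is data-derived.  The constants are package
defaults (the original method's constants live in prior literature and
are not restated here); burst counts are a relative concentration
proxy only, linear over ~10-fold ranges when the threshold statistics
stay background-dominated.  Transit rejection flags a recording when
the smoothed rate stays above `median + 5 * robust sd` for longer than
0.5 s — long enough to ignore single-bin spikes.

## Tracking (`centrikit.trackquant`)

Pipeline order is fixed: max projection -> exponential bleach
correction (`a e^{-bt} + c` on frame means; non-decaying movies pass
through with a warning) -> rolling-ball background subtraction ->
LoG detection -> greedy gap-free linking.  The rolling-ball background
is a grayscale opening with a **flat disk** of the given radius
(default 10 px): exactly idempotent and anti-extensive, preserving
features narrower than the disk.  The LoG scale is
`sigma = diameter/(2 sqrt 2)` with sub-pixel quadratic refinement;
`max_disp` (default 0.5 um) bounds frame-to-frame displacement, and
equidistant assignment ties break deterministically toward the lower
detection index.  Note that max-projecting shot-noisy stacks adds a
`sqrt(signal)` bias term to frame means that decays at half the bleach
rate; bleach-rate estimates are accurate (<5% error) for high-SNR
movies and biased low otherwise.

Intensities are the mean pixel value in a disk of the detection
diameter at the sub-pixel position; series are normalized to the WT
first-timepoint mean (set to 1) and aligned so the anchoring event
(NEB or centriole separation) is t = 0.

## Kinetics (`centrikit.kinetics`)

The breakpoint of the linear+plateau model is profiled over interior
timepoints and refined by bounded scalar minimization, with the other
parameters solved in closed form.  Model choice uses AICc (small-sample
Akaike; an extra-sum-of-squares F test is available as a config
alternative).  Fits are per embryo, on the mean of that embryo's
centriole series.  The "time at which levels start to decrease" is
operationalized as the argmax of a 3-frame moving average and is
undefined (flagged) when the maximum sits on the window boundary.  The
Lorentzian `baseline + A w^2/((t-t0)^2 + w^2)` reports amplitude
`baseline + A` and period proxy FWHM `= 2w`, from the fitted curve.

## Synthetic recruitment curves and movies

Growth curves cover the four canonical shapes (linear+plateau, linear,
rise-then-fall peaking before NEB, Lorentzian pulse), with per-embryo
S-phase lengths (default 13 min, sampled every 30 s), additive Gaussian
noise per timepoint and a multiplicative per-centriole brightness
factor.  No noise magnitudes are published for such curves; the
defaults (noise_sd = 0.1, centriole-to-centriole s.d. = 0.1 of the
signal scale) are declared in the config, not inferred from figures.
An optional coupling of the breakpoint to S-phase length supports the
growth-period/S-phase correlation analysis.  Movies render 2D Gaussian
spots (default sigma 0.25 um at 0.2 um/px) with Gaussian axial
attenuation across 17 slices 0.5 um apart, whole-frame exponential
bleaching (exact, by construction) and optional Poisson noise; pairs
separate at a constant rate along random directions.

Passing tests on these generators shows the pipeline recovers known
ground truth under the stated noise models; it does not certify
performance on real embryo data, where backgrounds are structured,
motion is not purely diffusive/linear and detection is aberrated.

## Problem sizes in tests

The test-suite and acceptance scenarios use desk-scale sizes chosen to
keep statistical power while running on one CPU: 10-s traces at
100-200-us bins for free-diffusion recovery (the 4.3-ms transit time is
resolved ~20-fold), sub-second 1-us-bin traces for triplet recovery,
model-generated curves at segment-scatter noise for alpha recovery
(see above), 100 simulated embryos for breakpoint statistics, and
128x128-px movies.  These are
the package's own scenario definitions; the generator defaults above
are not tuned per test.
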