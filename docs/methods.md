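# Methods

## Measurement model

The detector is radiochromic EBT-XD film recorded by a high-speed camera
(240 fps, 8-bit red channel, ~0.14 mm/px over a 9×9 cm² area). Three
post-processing stages recover the delivery time structure per pixel.

### 1. Pixel value → relative dose

Transmission densitometry with the full digital scale as white reference:
`OD = log10(2^b / (PV + 1))`, so a saturated pixel has OD 0 and OD grows as
the film darkens. The `+1` keeps PV = 0 finite; with `b = 8` the dynamic
range is OD ∈ [0, 2.408]. Net OD is relative to the **first recorded
frame**, which doubles as the per-pixel illumination/baseline reference (an
unirradiated-film reference scan would be the alternative convention; the
first-frame choice makes each recording self-referencing).

Relative dose follows `D = a + b·OD_net + c·OD_net^m`. The fit is a
trust-region nonlinear least squares with `a = 0`, `b` from a linear
prefit, `c = 1`, `m = 2` as start, `m ∈ (1, 5]` bounded, and `0^m := 0`.
Purely linear data leave `m` unidentifiable; the fit then returns `c = 0`
with a cleared `m_identifiable` flag instead of an arbitrary exponent.
Noise can push OD_net slightly negative; values are clipped to 0 before the
fractional power (raising only below a −0.05 tolerance), because fractional
powers of negatives are undefined and the clip is far below one 8-bit
quantization step at typical baselines.

The reference parameter set shipped as `REFERENCE_CALIBRATION`
(a = −7.48·10⁻³ Gy, b = 24.5 Gy/OD, c = 33.5 Gy/OD^m, m = 1.80) reproduces
the curve of the 0–50 Gy nine-film series for this film/readout
combination. For conventional flatbed scans a separate 2D polynomial
(OD order 0–3 × lateral-position order 0–2, plain linear least squares)
absorbs the scanner's lateral response.

### 2. Post-irradiation coloration correction

Every instantaneous dose deposit is assumed to produce the same coloration
kernel `k(t) = offset + c·log10(t + a)` (shipped reference:
offset 7.5·10⁻³, a 5.4·10⁻² s, c 5.7·10⁻⁴). The recorded response is the
causal discrete convolution of the delivered pulse with k, sampled on the
frame clock and truncated at `duration_s` (default 60 s, the stabilization
window the recording is required to cover past beam start). The forward
operator is a lower-triangular Toeplitz matrix; deconvolution is its exact
solve via Levinson recursion (`scipy.linalg.solve_toeplitz`), which mirrors
polynomial long division but is numerically stable at 10⁴–10⁵ samples. For
whole frame stacks the inverse filter (first column of the operator's
inverse) is computed once and applied to all pixels by FFT convolution.

No non-negativity is imposed on the recovered pulse: camera noise maps to
sign-alternating pulse samples whose integral is unbiased, whereas clipping
would bias the accumulation and hence Δt. An optional Tikhonov ridge and
pre-smoothing exist for short, very noisy single curves and are off by
default. Kernel fitting (offset, a, c) uses least squares against a known
pulse (a beam-monitor block pulse), initialized from the response tail with
a ∈ (10⁻⁴, 10] s bounded. The pulse is used exactly as measured so the
kernel's scale is identifiable; downstream only the kernel's *shape*
matters because the tail normalization removes scale.

### 3. Δt and PBS dose rate

The accumulation (cumulative sum of the pulse) is normalized to 100% at
the mean of its final tail window (1 s = 240 frames), then the first upward
crossings of 10% and 90% are located by linear interpolation on the
**running-maximum envelope** — accumulation is physically monotone, and the
envelope makes crossings unique under noise. Δt = t2 − t1; the PBS dose
rate with fractional threshold d is `(1 − 2d)·D_max/Δt` (absolute-d mode:
`(D_max − 2d)/Δt`). Pixels whose tail is non-positive, or below 5% of the
map maximum in the full-stack analyzer, are masked out. Distribution
statistics (mean, p5, p50, p95) use linearly interpolated percentiles.

## Delivery simulation

Spots are 2D Gaussians (σ 3.8 mm default, from 2D-Gaussian fits to
single-spot films) delivered in list order at constant rate over
`MU·time_per_MU` with peak dose `MU·(intercept + slope·I)`. The default
dose/MU line passes through (25 nA, 0.04 Gy/MU) and (215 nA, 0.06 Gy/MU);
time/MU defaults to 10⁻³ s/MU. Inter-spot transition time defaults to 0 —
scanning-magnet dead time is instead absorbed by linearly scaling all event
times to the measured total beam time, which is how the verification
workflow ties simulation to measurement. A warning flags spots shorter
than the delivery system's 3 ms minimum spot duration.

Per-pixel accumulation is stored analytically as piecewise-linear events
and sampled only on demand, so the nominal 0.1 mm / 10 kHz resolution costs
nothing; `sim_delta_t` solves the threshold crossings in closed form on the
ramps (the post-beam plateau equals the final dose exactly, which is what
tail averaging converges to). A 10 kHz brute-force curve sampler in the
test suite confirms equivalence to within one sample period.

## Registration and local gamma

Dose maps (not Δt maps) are registered first: the simulated dose is
resampled onto the measured grid and the translation maximizing the per-lag
normalized cross-correlation (cosine similarity over the overlap; lags
retaining < 30% of either map's energy are inadmissible) is refined by
parabolic peak interpolation. Because maps carry physical geometry the
shift is applied by moving the measured map's origin — the measured data
are never resampled.

Gamma uses local normalization at the candidate reference point (the right
convention for strongly inhomogeneous PBS dose-rate distributions). The
reference is interpolated bilinearly; candidates are sampled on a disc of
radius 3× the distance criterion at a step of min(ref pitch, DTA/10), so
with a 0.2 mm reference grid the discretization error on γ near 1 is below
the stated test tolerances. Truncation at 3×DTA cannot change a pass/fail
decision (a farther point alone contributes γ > 3). A pixel exactly on the
γ = 1 boundary passes (10⁻⁹ tie-break against float rounding). Evaluation
is restricted to the in-field (≥50% isodose) mask of the measured dose map.

## Synthetic footage generator

The generator is the forward model of the instrument and defines the
conditions of every end-to-end test: frame-binned per-pixel dose → causal
convolution with the kernel normalized to its post-roll value
(`k̂ = k/k(post_roll)`, tying the response tail to the true final dose, the
same convention the analysis' tail normalization adopts) → inverse
calibration to net OD → PV on top of a baseline of 220 (unirradiated film
under box illumination) → additive Gaussian noise of σ = 1 PV → rounding
and clipping to [0, 255]. Acquisition defaults follow the real setup:
240 fps, 1 s pre-roll, 60 s post-roll, 0.140625 mm camera pitch
(9 cm / 640 px). The 1 PV noise floor is a conservative choice for an
8-bit consumer sensor; true camera noise statistics and film-to-film
response variation are unreported for the setup, so both are exposed in
`FootageConfig` rather than hard-coded.

What the generator does *not* emulate: illumination drift and warm-up,
vignetting and mirror/lens geometry, film inhomogeneity, LET dependence of
the film response, and beam-current ripple. Passing end-to-end tests
therefore demonstrate the correctness and noise robustness of the
*analysis chain*, not the hardware's stability; the parameter-recovery
tests anchor the fitting machinery to reference parameter values
independently.

## Study sizes and numerical choices

The end-to-end QA study uses a 128×128 camera region at 0.35 mm pitch —
the native 0.14 mm pitch over 128 px would crop the 3×3 cm² field, and
0.35 mm remains far below the 2 mm distance criterion — with the simulated
reference Δt map on a 0.2 mm grid; the revisit study uses 64×64 at 0.7 mm.
Calibration inversion solves scalars by Brent bisection (round trip
~10⁻¹² Gy) and arrays by a 2²⁰-point monotone lookup refined with one
Newton step. Deconvolution of an N-sample record costs one O(N²) Levinson
solve shared by all pixels plus an FFT per pixel block; frame stacks are
streamed in pixel blocks so a full 65 s recording needs a few hundred MB.

## Known limitations

- Absolute dose is out of scope: the chain yields *relative* accumulation,
  so only Δt (and relative dose rate) is verified; ΔD would come from
  conventional film dosimetry.
- Camera frame rate bounds time resolution: Δt shorter than a few frame
  periods (≲20 ms at 240 fps) is systematically overestimated; the QA-grid
  deliveries used in the tests keep in-field Δt well above that.
- The Δt-threshold d is configurable (fractional default 10%, absolute
  supported); values in the accumulation's low-gradient regions make Δt
  noise-sensitive.
- The simulator models no energy/range physics, nozzle optics or
  monitor-chamber saturation beyond the commissioned dose/MU line.
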