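# Methods

This note documents the models, estimators and numerical choices behind
`sarcomech`, in the order the pipeline applies them, together with the
assumptions a user should know before trusting the numbers on real data.

## Phantom model (synthetic data)

A fiber is rendered as

```
I(x, y, z) = I₀ · envelope(v, z) · [1 + m·cos ψ(x, y)] + noise
```

* **Phase field.** The local striation-normal direction is the nominal
  fiber axis plus a smooth random deviation field: white noise low-pass
  filtered with a Gaussian kernel (correlation length 10 µm by default,
  emulating myofibril-bundle domains), centred and rescaled so its
  standard deviation equals the requested angular dispersion. The phase ψ
  is the least-squares integral of the target gradient
  `(2π/SL)(cos θ, sin θ)`: the mean (planar) component is added
  analytically and the fluctuating part solved with a DCT Poisson solver.
  Because that projection is not exact for a non-integrable direction
  field, ground truth (`true_cas`) is computed from the *rendered* phase
  gradient, not from the nominal distribution — recovery tests then
  compare like with like.
* **Verniers.** Each requested vernier adds `± atan2(y−y₀, x−x₀)` to ψ —
  an edge dislocation of the grating with ±2π winding, i.e. one
  terminating fringe forming the classic Y. Sites are drawn uniformly in
  the fiber core with ≥ 4 SL separation; the count is rejected when the
  core cannot hold it. Dislocation lines run through all slices.
* **Envelope.** Circular cross-section of the given diameter: each slice
  shows the chord band at its depth, with a 0.8 px Gaussian edge.
* **Noise.** Optional Poisson resampling (scaled by `photon_scale`,
  emulating PMT counting statistics) plus additive Gaussian read noise.
  The real detector's noise statistics are unknown to us; this model is a
  parameterised stand-in, not a claim.

Defaults describe the acquisition this package targets: 2.2–3.1 µm
sarcomeres, 30–60 µm fiber diameters, 0.195–0.25 µm pixels, 200 × 200 µm
full fields. The phantom does **not** model the optical point-spread
function, SHG polarization dependence, depth-dependent attenuation or
photobleaching; passing recovery tests on phantoms therefore validates
the *estimators*, not the microscope.

Force traces follow the two experimental designs. pCa staircases have
plateaus given exactly by the Hill relation, with 0.2 s triangular
positive spikes early in each step standing in for manual solution
exchanges. Stretch series jump instantaneously to
`F_eq + A₁ + A₂` and decay double-exponentially. Default synthetic step
durations (30–60 s) compress the experimental 5-minute holds; the decay
is fully sampled relative to its time constants, which is what matters to
the fit.

## Orientation estimation and CAS

The boundary tensor at scale σ combines an odd part (outer product of the
Gaussian gradient, γ-normalised with σ²) and an even part (matrix square
of the Gaussian Hessian, σ⁴), so that a sinusoidal pattern excites the
tensor roughly phase-independently. Components are smoothed with a
Gaussian of width σ before the eigen-decomposition. Defaults: σ = SL/4
(captures the striation edge structure), tensor smoothing = σ. The
principal eigenvector gives the striation-normal orientation θ ∈ (−90°,
90°]; the trace gives the energy used for masking and weighting. All
angle statistics are axial (doubled-angle embedding).

Masking: the fiber region is the set of pixels whose intensity exceeds
10 % of the reference (stack maximum; min-referenced so the mask is
invariant under affine intensity changes), morphologically closed over
the striation period so it forms a solid envelope, then eroded by the
filter support (≈ 2σ + smoothing) — the fiber *edge* has its own
orientation (along the fiber) and would otherwise bias CAS by up to 0.06.
Within that region, pixels below the 0.10 energy quantile are dropped. A
higher quantile (0.25) was measured to sample in-fiber pixels
non-uniformly and bias CAS by ~0.03 at 40° dispersion, which is why the
default is 0.10.

**Main axis.** Two estimators are provided. `estimate_main_axis` is the
energy-weighted circular mean of the doubled orientation angles — correct
for answering "what is the average myofibril direction of this field".
The pipeline, however, references CAS to `estimate_main_axis_geometric`:
a centerline fit of the fiber envelope (per-column centroids of the
intensity mask, excluding frame-clipped columns, with a moment-based
fallback). The reason is statistical: in a strongly disordered fiber the
orientation average tracks the particular disorder realization (errors of
20–45° were measured at 40° dispersion), which would flatten the very
deviations CAS measures; the geometric axis is defined by the fiber, not
by its disorder. On phantoms it recovers the nominal axis to < 0.1°.

CAS of a slice is the unweighted mean of cos Δθ over masked pixels, with
Δθ ∈ [0°, 90°] the axial difference to the main axis; the stack CAS is
the pixel-count-weighted mean over slices (more fiber, more weight). With
these choices the mean recovery error on noise-free phantoms is ≤ 0.01
across dispersions 0–40°. `cos Δθ` (not `cos 2Δθ`) is used — consistent
with CAS = 1 meaning parallel and with a soft penalty for small
deviations; this is an interpretation choice and is recorded here.

## Vernier detection

Per slice, the image is band-pass filtered around the striation frequency
1/SL (Gaussian annulus, 30 % relative bandwidth) with a half-plane
selection along the main axis, giving a complex analytic striation field.
Verniers are the points where the closed-loop winding of its phase over a
2 × 2 plaquette is ±2π. Safeguards: detections are restricted to the
intensity-envelope core eroded by 1.5 SL (*not* the energy mask — the
striation amplitude vanishes exactly at a defect core, so an energy mask
would punch holes at the defects); detections in regions whose local
striation amplitude is below 0.3 × the in-fiber median are discarded
(noise creates singularity pairs only where signal is weak); and
detections within SL/2 merge into one (one dislocation = one Y). On
phantoms this yields 8/8 detections of inserted defects with zero false
positives over clean fibers up to 20° dispersion, and ≥ 0.8 recall at
read noise of 10 % of the modulation amplitude.

VD divides the vernier count by the evaluated area. The pipeline default
uses the masked fiber area (background would dilute a density); the
frame-area convention used by the phantom ground truth is available via
`use_frame_area`. The stretch-corrected VD multiplies by
`SL_current / SL_reference`: sarcomere boundaries per unit length — and
with them vernier opportunities in a fixed field of view — scale as 1/SL.
The correction formula is this package's documented assumption; outputs
flag it.

## Geometry

Slice validity: a slice enters the evaluation iff ≥ 10 % of its pixels
reach ≥ 10 % of the stack maximum (both bounds inclusive; the inclusive
boundary is a documented convention). Width per slice is the extent,
perpendicular to the main axis, of the largest connected component above
the relative threshold (default 0.10 of stack max, hence gain-invariant).
The diameter is the peak amplitude of a Gaussian fitted to width vs z —
for a circular cross-section the width-vs-depth curve is a semicircle
whose peak is the diameter; the Gaussian mismatch biases the peak by
≤ 5 %, which is accepted and covered by tests. A non-convergent fit falls
back to the maximum width and is flagged. CSA = π(D/2)².

SL per slice: the slice is rotated so the fiber is horizontal, rows
containing fiber are averaged into one profile (averaging was chosen over
a single line for noise robustness; the choice is recorded in output
metadata), and the magnitude spectrum is scanned. Bins below 0.08 µm⁻¹
form the DC/envelope peak; among the remaining local maxima the largest
is the striation peak — by construction the second-highest peak overall,
so a 40 % second harmonic cannot displace the fundamental. The peak
frequency is refined by parabolic interpolation of the log-magnitude, and
a peak weaker than 3 × the spectral noise floor raises "no striation
signal" rather than returning a number. Stack SL is the arithmetic mean
over valid slices (failed slices are skipped and logged). Recovery on the
3 × 3 grid (SL 2.2/2.6/3.1 µm × diameter 30/45/60 µm): SL within 0.5 %,
diameter within 4.5 %.

## Mechanics

*Steady state per pCa step.* Samples more than 5 robust sigmas above a
1 s rolling median are treated as solution-exchange spikes and removed;
the steady force is the median of the final 20 % of the quiet samples
(≥ 50 required). A linear drift larger than 1 % of the steady force per
10 s flags the step as non-steady. Gate width, quiet fraction and drift
tolerance are configurable; the original instrument's criteria are not
published, so these defaults are this package's choices.

*Hill fit.* Nonlinear least squares of
`F = F_max / (1 + 10^{h(pCa−pCa₅₀)})`, multi-started at h ∈ {1, 2, 4, 8}
with the best residual kept; the saturating step (pCa 4.92 in the
standard protocol) supplies the maximal force. Exact data are recovered
to 10⁻⁶ relative; under 2 % multiplicative noise the pCa₅₀ bias is
< 0.001 and the RMSE < 0.01 over 100 replicates.

*Unit conventions.* 1 µN/µm² = 1 MPa: specific force is reported in
N/cm² (× 100) and stresses in kPa (× 1000). Force per diameter (µN/µm)
is also emitted, as the diameter-normalised variant used in
structure–force calibration.

*Step stretch.* F_max is the window maximum (absolute force by default; a
baseline-subtracted convention is a config switch, since the original
convention is not stated). The decay from the peak is fitted with the
double-exponential model under non-negative amplitude bounds; a single
exponential is used instead when the second term improves the residual by
less than 5 % (relative) — the identifiability margin between the
"double-exponential" and plain "exponential" descriptions. τ₁ < τ₂ by
convention. Strain is the actuator position over the initial clamped
length, cumulative across steps. A fitted F_eq ≥ F_max flags a
non-decaying window; values are still reported. Rupture is a > 80 % force
drop within 1 s; the last pre-collapse sample gives rupture stress and
strain, and traces without a collapse return a censored summary.

## Calibration

Each structure–function pair is a simple linear regression (the
calibration is deliberately univariate; groups are carried as labels and
pooled, since pooling ordered and disordered cohorts is what widens the
dynamic range enough to calibrate). Pearson r is computed from the
centred moments and its two-sided p-value from
`t = r√((n−2)/(1−r²))` with n−2 degrees of freedom — implemented
directly, with the established library used as a cross-check in tests,
not as the implementation. Prediction intervals use the standard
linear-model prediction variance
`s²(1 + 1/n + (x−x̄)²/Sxx)` with t quantiles; requests more than 50 %
outside the training range are flagged as extrapolation. No
multiple-testing correction is applied across the four pairs; outputs
note this. Simulated calibrations (n = 30, noise sd 0.05 on a slope-2
relation) give an unbiased slope (SE ≈ 0.13, as the closed form
predicts), r > 0.9 in ≈ 97 % of replicates, and 95 % prediction-interval
coverage within sampling error.

## Determinism and problem sizes

Every stochastic component takes a seed; a pipeline configuration plus
seed reproduces all outputs byte-for-byte (fixed CSV float formatting,
sorted JSON keys, content-hash provenance instead of timestamps). Tests
and the acceptance script run phantom fields of 80–200 µm at 0.195–0.25
µm pixels and replicate counts of 10–200 per statistic — sizes chosen so
the full validation executes in well under a minute on one CPU while
keeping every tolerance binding.

## Known limitations

* Orientation analysis is per-slice 2D with stack aggregation; there is
  no through-plane (3D) orientation tensor.
* The cross-section is assumed circular; flattened or branched fibers
  will bias diameter and CSA (branching appears in severely dystrophic
  fibers).
* The vernier–phase-singularity equivalence operationalises "Y-shaped
  deviation"; defects that shift striations by much less than half a
  period produce no winding and are not counted.
* The stretch-corrected VD rests on the 1/SL scaling assumption stated
  above.
* Phantom realism bounds what the tests prove (no PSF, no polarization,
  no attenuation); on real stacks the wavelet pre-filter
  (`denoise_wavelet`, hard-thresholded starlet) is available for
  low-SNR acquisitions such as stretch series, where intensity drops
  with sarcomere elongation.
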