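# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `fractometry` package.

## Field reconstruction from knife-edge images

A gradient-encoding microscope records four half-blocked intensity images
Iₓ⁺, Iₓ⁻, I_y⁺, I_y⁻ plus a background frame B.  The normalized differences
encode the transverse phase gradient up to an instrument constant:
gₓ = (1/gain)·(Iₓ⁺ − Iₓ⁻)/(Iₓ⁺ + Iₓ⁻), and analogously in y.  The
proportionality constant is an optical calibration that cannot be derived
from the images; it is exposed as `gain` (default 1) and shared by the
synthetic forward model, so round trips are exact by construction.  The
amplitude is A = (Iₓ⁺ + Iₓ⁻)/B; the y pair gives an independent estimate
whose maximum relative discrepancy is recorded as a quality metric.

**Fourier integration.**  The combined gradient ∇φ = gₓ + i·g_y has
transform 2πi(fₓ + i·f_y)·Φ with fₓ, f_y in cycles per pixel.  The
integrating kernel is NF = 1/(2π(fₓ + i·f_y)) with NF(0) = 0, which places
i·Φ in the spectrum: the imaginary part of the inverse transform is the
mean-removed phase (times the calibration factor CF, default 1), and the
real part is a numerical residue that vanishes for consistent (curl-free)
gradients — a built-in consistency diagnostic.  Setting the DC bin to zero
fixes the additive gauge: reconstructed phase always has zero mean.  The
integrator is linear and exact on periodic band-limited phases; non-periodic
scenes should use `pad_factor ≥ 2` (edge padding before the FFT, cropping
after), which brings an isolated Gaussian bump to <1% relative RMSE.

**Units and conventions.**  Images are row-major with x along columns and
y along rows, origin top-left.  Wavelength defaults to 1.064 μm (the
swept-source band of the instrument class this models) and pixel pitch to
0.2 μm — chosen to sample a ~0.75-NA diffraction limit at this wavelength
with margin; both are explicit parameters everywhere.
All log-log fits use natural logarithms (slopes are base-independent; MSE
values are in nat²); window widths are reported in decades.

## FTLS, the ALS profile and the density correlation

The far field is the centered unnormalized FFT of A·e^{iφ}, optionally
Hann-apodized and zero-padded; Parseval then reads Σ|E|² = Σ|S|²/N_pixels.
Frequency axes follow the standard FFT layout, so on even grids the
negative Nyquist bin has no positive partner (axes are exactly symmetric
on odd grids only).

Each pattern pixel maps to a polar scattering angle through
sinθ = k_r·λ/2π; evanescent pixels (sinθ > 1) are discarded, and
intensities are averaged in bins of q = (4π/λ)sin(θ/2) one frequency-pixel
wide (empty bins dropped).

The density-correlation curve is the Wiener–Khinchin route: the inverse 2D
transform of |S|² is the circular spatial autocorrelation of the field on
the image grid.  Its modulus (guaranteeing positivity for log fitting) is
radially averaged in one-pixel lag bins, normalized to the zero-lag value,
and retained for lags between one pixel and half the unpadded field of
view.  A standing property test checks this against a literal O(N⁴)
shift-multiply-sum autocorrelation to 1e−6.

**Incident-field subtraction.**  For profiling, the chain analyzes the
scattered component E − 1 by default (`subtract_incident=True`).  The
correlation of interest is that of the *density fluctuation*; the
unscattered unit background contributes only the transform of the
rectangular field of view, which dominates small angles and pins the
fitted FD near 3 regardless of the object.  Set the flag off to analyze
the total field.

## Fractal dimension and the fractal window

A mass fractal has C_ρ(r) ∝ r^(−α) with FD = 3 − α.  The overall fit is
ordinary least squares of log C on log r over the analysis range
(default: r_lo = 2 pixels, the resolution criterion, to r_hi = the
segmented cell's equivalent radius, or a quarter of the field of view
without a mask); its mean squared residual is the FD MSE2 feature — a
per-cell measure of how well a single power law describes all probed
scales.

The fractal window excludes the short- and long-distance segments where
scaling fails: local slopes from centered (2w+1)-bin regressions
(w = 2; windows truncate to ≥3 bins at the edges so boundary bins receive
slopes) are *eligible* where they are at least as steep as the overall
slope (closed under equality, so a pure power law is eligible everywhere).
Among contiguous eligible runs of at least 5 bins and 0.3 decades, the
detector maximizes prominence = Σ(s_overall − s_local)·Δlog₁₀r; ties go to
the longer run, then the smaller r_min.  If no run qualifies the whole
analysis range is returned with a `fallback` flag (prominence 0).  On a
constructed flat/−1/flat curve the detected bounds land within one bin of
the true break points and the within-window FD equals 2.00 ± 0.02.

**The 17-feature catalog (version 1).**  Fixed order: fd, fd_mse2,
fd_with_fw, fd_fw_mse, fw_width, fw_r_min, fw_r_max, fd_width,
fw_prominence, als_log_mean, als_log_sd, als_log_skew, als_log_kurt,
als_slope, als_frac_lowq, als_frac_midq, als_frac_highq.  The first five
named fractal quantities are the text-book set (overall FD and its MSE,
FD within the window, window width, and fd_width = |FD − FD-with-FW|);
the remainder are a documented, versioned completion: the four moments and
the slope of log S(q), and the energy fractions in three q bands split at
the 33rd/66th percentiles of the propagating q range (a parameter-free
partition; the fractions always sum to 1).  ALS statistics are computed
over bins with q > 0; profiles constant to machine precision get exactly
zero moments and slope.  Degenerate scenes (no scattered energy) are
profiled against the total field, yield FD = 3, and carry a `degenerate`
flag.

## Bulk morphology and dry mass

Segmentation thresholds the phase map (Otsu by default, or an explicit
threshold), keeps the largest connected component and fills holes; Otsu is
a pragmatic default and is configurable.  OPL = φ·λ/2π;
dividing by the specific refractive increment (0.19 ml/g ≡ 0.19 μm³/pg)
gives dry-mass surface density in pg/μm², integrated over the mask for
total dry mass.  The conversion puts a 4–8 nm OPL sensitivity at
0.0211–0.0421 pg/μm² (the often-quoted ~0.02–0.04 figure; note the unit is
per μm², which dimensional analysis requires).

## Synthetic phantoms

* **Sphere** — weak-phase projection φ(ρ) = (2π/λ)Δn·2√(R² − ρ²), A ≡ 1
  (anomalous-diffraction regime).  Its first scattering minimum sits at
  the first zero of the ball transform, kR·sinθ = 4.4934 (tan u = u) —
  *not* at the Airy position; the flat-phase **disk** phantom is the Airy
  reference (sinθ = 0.61λ/R).  Agreement with the Mie series is asserted
  on minima positions, not absolute intensities, because the projection
  neglects vectorial effects.
* **Mie series** — coefficients from Riccati–Bessel functions via scipy's
  spherical Bessel routines, truncated at N = ⌈x + 4x^{1/3} + 2⌉, valid
  for real index and x ≤ 200.  The test suite cross-checks it against an
  independently coded downward logarithmic-derivative recurrence to 1e−6
  and against the Rayleigh (1 + cos²θ) limit at x = 0.05 to 1%.
* **Fractal fields** — unit-variance complex Gaussian spectra shaped by
  k^(−β/2) (DC zeroed), inverse-transformed, RMS-normalized and windowed
  by a cosine-tapered disk envelope; amplitude optionally tracks phase.
  Pure functions of (spec, seed).
* **Knife-edge forward model** — central (not spectral) differences, so
  forward and inverse are genuinely different discretizations and round
  trips test the integrator honestly (tolerance 1%, not machine
  precision); |gain·∇φ| is clipped below 1 to keep intensities
  nonnegative; optional additive Gaussian noise, clipped at zero.
* **Cohorts** — Gaussian feature tables with per-class mean shifts,
  defaulting to the three-class, 2000-cells-per-class, 17-feature design
  of a subtype-profiling study.

**FD-recovery study conditions.**  The β-sweep validation uses
calibration-grade phantoms: phase RMS 0.1 rad (so E − 1 ≈ iφ and the field
correlation equals the phase autocorrelation, whose exponent is known:
α = 2 − β for β < 2), envelope radius equal to the inscribed circle
(12.8 μm at 128×0.2 μm, so the envelope's own autocorrelation decay is
negligible over the fit range), and fit range r = 2–8 pixels
(0.4–1.6 μm).  Under these conditions the pipeline FD means over 20 seeds
are ≈1.9/2.5/2.8 for β = 1/2/3 — strictly monotone — and agree with
per-realization brute-force real-space fits to ~1e−15 (the two routes are
mathematically identical; the oracle's value is its independence from the
FFT code path).

**What the phantoms do not emulate.**  Real cells are strong-phase objects
(multiple radians): there the e^{iφ} nonlinearity and the cell's own
compact support compress the FD-versus-spectrum relationship, which is why
the recovery study runs in the weak-phase regime.  Phantoms are also
noise-free by default, perfectly isotropic in statistics, and contain no
subcellular compartment structure; passing tests demonstrate the
correctness of the measurement chain, not biological realism.

## Statistics

Cliff's delta is computed by the average-rank method (ties contribute
zero), which an enumeration oracle confirms pair-for-pair; AUROC comes
from a threshold-sweep ROC with trapezoidal area, and the identity
AUROC = (δ + 1)/2 holds to 1e−12 including ties.  "Linear regression
classifiers" are literal unregularized least squares on ±1 one-vs-all
indicators with intercept, solved minimum-norm so rank-deficient designs
(duplicated features) leave fitted scores unchanged; training AUROC is
reported unoriented.  Per-feature ranking uses the raw feature as score
with orientation max(a, 1 − a), averaged over classes.  No p-values or
multiple-testing corrections are computed anywhere — effect sizes and
AUROC are sample-size-stable by design.  Z-scoring drops zero-variance
features and is idempotent; the z-scored matrix can be exported for any
external embedding tool (no embedding is computed here).

## Pipeline

Batches process per cell with failure isolation (one corrupted input never
aborts a run; failures go to a machine-readable ledger).  Outputs carry the
config hash and package version; identical inputs + config produce
byte-identical CSVs.  I/O uses multi-page float32 TIFF stacks (knife-edge
order Iₓ⁺, Iₓ⁻, I_y⁺, I_y⁻, B; field order amplitude, phase) with JSON
sidecars, and two-column CSVs with `#` metadata headers for profiles.

## Known limitations

* The knife-edge gain and CF are user calibration inputs; absolute phase
  accuracy on real instruments depends on them.
* Scalar diffraction only: no partial coherence, polarization, or
  multiple-scattering model.
* The FW detector's local-slope estimate is resolution-limited near curve
  ends; break points are located to one bin at 20 bins/decade.
* Otsu-on-phase segmentation underestimates radii of smooth-edged objects
  by up to a pixel (threshold at mid-height).
* The 17-feature catalog beyond the five text-book quantities is a
  versioned surrogate; catalog_version guards downstream compatibility.
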