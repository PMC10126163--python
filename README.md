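# fractometry

Single-cell **biophysical fractometry**: label-free morphological profiling of
cells through the fractal statistics of their dry-mass distribution.

Quantitative phase imaging (QPI) measures the optical path delay φ(x, y)
through a cell, which is proportional to its dry-mass surface density.
Intracellular mass is organized statistically self-similarly over a limited
range of length scales, and that organization changes with cell state —
tumor subtype, drug response, cell-cycle phase.  This package turns a
per-cell complex optical field into a compact, physically interpretable
fractal feature vector, and provides the cohort statistics used to compare
thousands of cells without p-value inflation.

The pipeline:

1. **Field reconstruction** — four knife-edge (half-blocked) intensity
   images encode the phase-gradient components
   ∂φ/∂x ∝ (Iₓ⁺ − Iₓ⁻)/(Iₓ⁺ + Iₓ⁻); the phase is recovered by complex
   Fourier integration of ∇φ = ∂φ/∂x + i∂φ/∂y, and the amplitude is the
   background-normalized pair sum A = (Iₓ⁺ + Iₓ⁻)/B.
2. **Fourier-transform light scattering (FTLS)** — the field E = A·e^{iφ}
   is propagated numerically to the far field, S(kₓ, k_y) = F[E]; ring
   averaging over constant q = (4π/λ)sin(θ/2) gives the angular
   light-scattering (ALS) profile.
3. **Density correlation and fractal dimension** — by the Wiener–Khinchin
   theorem the inverse transform of |S|² is the spatial autocorrelation
   C_ρ(r) of the density fluctuation; a mass fractal obeys
   C_ρ(r) ∝ r^(−α) with **FD = 3 − α**.  A *fractal window* (FW) detector
   finds the range of r where the power law actually holds, and the fit is
   repeated inside it.
4. **Feature catalog** — 17 fractal/ALS features per cell (FD, FD MSE2,
   FD-with-FW, FW bounds/width/prominence, log-ALS moments, ALS slope and
   band energies), plus bulk features (area, OPL, dry mass via the
   0.19 ml/g refractive increment).
5. **Profiling statistics** — z-scoring, Cliff's delta effect sizes,
   one-vs-all AUROC feature ranking, unregularized least-squares
   classifiers, Spearman correlation structure.

Everything is testable end to end on synthetic phantoms with known truth:
weak-phase spheres (with an exact Mie-series oracle), flat disks (Airy
oracle), random fields with prescribed power-law spectra (known fractal
exponent), and labeled Gaussian cohorts.

## Worked example

`examples/03_fractal_dimension.py` generates random fields whose phase has
an isotropic k^(−β) power spectrum and estimates FD through the full chain:

```
beta = 1.0:  FD = 1.844 +/- 0.207  (5 seeds)
beta = 2.0:  FD = 2.429 +/- 0.152  (5 seeds)
beta = 3.0:  FD = 2.762 +/- 0.075  (5 seeds)

17-feature profile of one phantom (catalog v1):
  fd = 2.044, fd_with_fw = 1.522, fw = [1.60, 3.40] um (0.33 decades)
  fd_mse2 = 0.0088, als_slope = -1.68
```

FD rises with β because smoother mass distributions (steeper spectra) are
closer to space-filling; `fd` is the overall log-log fit and `fd_with_fw`
the refit inside the detected fractal window.  The other examples cover
phase reconstruction (`01`), scattering oracles (`02`), dry mass (`04`)
and cohort statistics (`05`); each prints the numbers it computes and one
line on what they mean.

A thin CLI wraps the same library for batch work:

```sh
fractometry simulate --kind sphere --out sim/ --n 10 --as-knife-edge
fractometry features sim/*.tiff --out run/
fractometry profile run/features.csv --out stats/
fractometry validate
```

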