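"""Fractal dimension of a synthetic field with known power-law spectrum.

Generates phantoms whose phase has an isotropic k^(-beta) spectrum, runs
the full chain (far field -> density correlation -> log-log fit -> fractal
window), and prints the estimated FD per beta.  FD should increase with
beta: smoother mass distributions have higher fractal dimension.
"""

import numpy as np

import fractometry as fm
from fractometry.scattering import scattered_field

for beta in (1.0, 2.0, 3.0):
    fds = []
    for seed in range(5):
        field = fm.fractal_phantom(fm.FractalFieldSpec(
            beta=beta, grid_size=128, seed=seed,
            phase_rms=0.1, envelope_radius_um=12.8,
        ))
        pattern = fm.far_field_pattern(scattered_field(field))
        curve = fm.density_correlation(pattern)
        fit = fm.fit_overall_fd(curve, r_lo=0.4, r_hi=1.6)
        fds.append(fit.fd)
    print(f"beta = {beta}:  FD = {np.mean(fds):.3f} +/- {np.std(fds):.3f}  (5 seeds)")

# full 17-feature profile of one cell-like phantom
field = fm.fractal_phantom(fm.FractalFieldSpec(beta=2.0, grid_size=128, seed=0))
profile = fm.fractal_profile(field)
d = profile.as_dict()
print(f"\n17-feature profile of one phantom (catalog v{profile.catalog_version}):")
print(f"  fd = {d['fd']:.3f}, fd_with_fw = {d['fd_with_fw']:.3f}, "
      f"fw = [{d['fw_r_min']:.2f}, {d['fw_r_max']:.2f}] um "
      f"({d['fw_width']:.2f} decades)")
print(f"  fd_mse2 = {d['fd_mse2']:.4f}, als_slope = {d['als_slope']:.2f}")
print("fd is the overall power-law fit (FD = 3 - alpha); fd_with_fw refits")
print("inside the detected fractal window where scaling actually holds.")
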