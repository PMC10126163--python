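"""Reconstruct a quantitative phase map from knife-edge images.

Builds a smooth phase object, runs the knife-edge forward model (the four
half-blocked intensity images a gradient-encoding microscope records), and
recovers the phase by complex Fourier integration.  The printed relative
RMSE shows how closely the integrated phase matches the ground truth.
"""

import numpy as np

import fractometry as fm

n = 128
yy, xx = np.mgrid[0:n, 0:n]
phase = 1.5 * np.exp(-(((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / (2 * 10.0**2)))
truth = fm.ComplexField(
    amplitude=np.ones((n, n)), phase=phase, wavelength_um=1.064, pixel_um=0.2
)

ke = fm.knife_edge_forward(truth, background=1.0, gain=1.0)
rec = fm.reconstruct_field(
    ke, gain=1.0, cfg=fm.IntegrationConfig(pad_factor=2),
    wavelength_um=1.064, pixel_um=0.2,
)

target = truth.phase - truth.phase.mean()
rel_rmse = np.sqrt(np.mean((rec.phase - target) ** 2)) / np.sqrt(np.mean(target**2))
print(f"peak phase (truth):        {truth.phase.max():.4f} rad")
print(f"peak phase (reconstructed): {rec.phase.max() - rec.phase.min():.4f} rad span")
print(f"phase round-trip relative RMSE: {rel_rmse:.2e}")
print(f"amplitude x/y-pair discrepancy: {rec.meta['amplitude_xy_discrepancy']:.2e}")
print("A relative RMSE below 1e-2 means the integrator faithfully inverts")
print("the knife-edge gradient encoding for an isolated smooth object.")
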