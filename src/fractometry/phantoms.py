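"""Synthetic phantoms: every input the pipeline needs, with known truth.

Four generators cover the pipeline end to end:

* **Sphere phantoms** — weak-phase projections of homogeneous spheres
  (microbead surrogates), whose scattering has an exact Mie-series oracle.
* **Flat-phase disks** — circular apertures whose far field is the Airy
  pattern (first minimum at sinθ = 0.61·λ/R), the classical position check
  for the FTLS chain.
* **Fractal fields** — random phase fields with a prescribed isotropic
  power-law spectrum k^(−β), i.e. known correlation scaling, the test bed
  for fractal-dimension recovery.
* **Knife-edge forward model** — turns any field into the four half-blocked
  intensity images, inverting the reconstruction equations, with optional
  detector noise.
* **Labeled cohorts** — Gaussian feature tables with prescribed per-class
  shifts for the profiling statistics.

Every generator is a pure function of (spec, seed); the spec and seed are
embedded in the output metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import ParameterError
from .mie import X_MAX, mie_intensity
from .phase_field import ComplexField, KnifeEdgeSet
from .profiling import FeatureTable
from .scattering import ALSProfile

__all__ = [
    "SphereSpec",
    "FractalFieldSpec",
    "ClassSpec",
    "CohortSpec",
    "sphere_phantom",
    "disk_phantom",
    "mie_als",
    "fractal_phantom",
    "knife_edge_forward",
    "synth_cohort",
]


def _grid(grid_size: int, pixel_um: float) -> tuple[np.ndarray, np.ndarray]:
    c = (grid_size - 1) / 2.0
    ax = (np.arange(grid_size) - c) * pixel_um
    return np.meshgrid(ax, ax)


@dataclass(frozen=True)
class SphereSpec:
    """Homogeneous-sphere (microbead) phantom parameters."""

    radius_um: float
    delta_n: float
    n_medium: float = 1.33
    wavelength_um: float = 1.064
    pixel_um: float = 0.2
    grid_size: int = 256

    def __post_init__(self) -> None:
        if not (self.radius_um > 0 and self.n_medium > 0
                and self.wavelength_um > 0 and self.pixel_um > 0):
            raise ParameterError("physical scalars must be positive")
        if not self.radius_um < self.grid_size * self.pixel_um / 2:
            raise ParameterError("sphere must fit inside the field of view")

    @property
    def size_parameter(self) -> float:
        return 2.0 * np.pi * self.n_medium * self.radius_um / self.wavelength_um


def sphere_phantom(spec: SphereSpec) -> ComplexField:
    """Weak-phase projection of a homogeneous sphere.

    Phase is the chord length through the sphere times the index contrast:
    φ(ρ) = (2π/λ)·Δn·2√(R² − ρ²) inside ρ < R, zero outside; amplitude is 1
    (anomalous-diffraction regime, absorption neglected).  Peak phase at the
    center is (2π/λ)·Δn·2R.
    """
    X, Y = _grid(spec.grid_size, spec.pixel_um)
    rho2 = X**2 + Y**2
    chord = np.zeros_like(rho2)
    inside = rho2 < spec.radius_um**2
    chord[inside] = 2.0 * np.sqrt(spec.radius_um**2 - rho2[inside])
    phi = (2.0 * np.pi / spec.wavelength_um) * spec.delta_n * chord
    return ComplexField(
        amplitude=np.ones_like(phi),
        phase=phi,
        wavelength_um=spec.wavelength_um,
        pixel_um=spec.pixel_um,
        meta={"phantom": "sphere", "spec": asdict(spec)},
    )


def disk_phantom(
    radius_um: float,
    phase_rad: float = 0.1,
    wavelength_um: float = 1.064,
    pixel_um: float = 0.2,
    grid_size: int = 256,
) -> ComplexField:
    """Flat-phase circular disk: the Airy-pattern reference object.

    For weak phase the scattered field is the transform of the disk
    indicator, so the first ALS minimum sits at sinθ = 0.61·λ/R.
    """
    if not radius_um < grid_size * pixel_um / 2:
        raise ParameterError("disk must fit inside the field of view")
    X, Y = _grid(grid_size, pixel_um)
    phi = np.where(X**2 + Y**2 < radius_um**2, float(phase_rad), 0.0)
    return ComplexField(
        amplitude=np.ones_like(phi),
        phase=phi,
        wavelength_um=wavelength_um,
        pixel_um=pixel_um,
        meta={"phantom": "disk", "radius_um": radius_um, "phase_rad": phase_rad},
    )


def mie_als(spec: SphereSpec, theta_grid) -> ALSProfile:
    """Analytic Mie ALS profile of the spec'd sphere on a polar-angle grid.

    Relative index m = 1 + Δn/n_medium, size parameter x = 2π·n_med·R/λ;
    unpolarized intensity mapped to q = (4π/λ)·sin(θ/2).
    """
    x = spec.size_parameter
    if not 0.0 < x <= X_MAX:
        raise ParameterError(f"size parameter {x:.3g} outside (0, {X_MAX}]")
    theta = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    if np.any(np.diff(theta) <= 0):
        raise ParameterError("theta_grid must be strictly increasing")
    m = (spec.n_medium + spec.delta_n) / spec.n_medium
    s = mie_intensity(m, x, theta)
    q = (4.0 * np.pi / spec.wavelength_um) * np.sin(theta / 2.0)
    return ALSProfile(
        q=q,
        s=s,
        counts=np.ones_like(q, dtype=int),
        theta=theta,
        wavelength_um=spec.wavelength_um,
        meta={"model": "mie", "m": m, "x": x, "spec": asdict(spec)},
    )


@dataclass(frozen=True)
class FractalFieldSpec:
    """Random field with isotropic power-law phase spectrum ∝ k^(−β)."""

    beta: float
    grid_size: int = 128
    pixel_um: float = 0.2
    envelope_radius_um: float | None = None  # default: 40% of field extent
    amplitude_contrast: float = 0.0
    phase_rms: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if not (self.grid_size > 8 and self.pixel_um > 0 and self.phase_rms > 0):
            raise ParameterError("invalid grid/pixel/phase_rms")


def fractal_phantom(
    spec: FractalFieldSpec, wavelength_um: float = 1.064
) -> ComplexField:
    """Cell-like field with a prescribed fractal (power-law) phase spectrum.

    A unit-variance complex Gaussian spectrum is shaped by k_r^(−β/2)
    (DC zeroed), inverse-transformed, normalized to ``phase_rms`` radians
    RMS, and windowed by a cosine-tapered disk envelope so the object is
    compactly supported.  Amplitude is 1 + amplitude_contrast · (phase
    normalized to unit peak).  Deterministic given (spec, seed).
    """
    n = spec.grid_size
    rng = np.random.default_rng(spec.seed)
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    kr = np.hypot(fx, fy)
    shape = np.zeros_like(kr)
    nz = kr > 0
    shape[nz] = kr[nz] ** (-spec.beta / 2.0)
    noise = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    phi = np.fft.ifft2(noise * shape).real
    phi -= phi.mean()

    env_r = spec.envelope_radius_um
    if env_r is None:
        env_r = 0.4 * n * spec.pixel_um / 2.0 * 2.0  # 40% of field extent
    X, Y = _grid(n, spec.pixel_um)
    rho = np.hypot(X, Y)
    taper_start = 0.8 * env_r
    env = np.ones_like(rho)
    ramp = (rho >= taper_start) & (rho < env_r)
    env[ramp] = 0.5 * (1.0 + np.cos(np.pi * (rho[ramp] - taper_start) / (env_r - taper_start)))
    env[rho >= env_r] = 0.0

    support = env > 0
    rms = np.sqrt(np.mean(phi[support] ** 2)) if support.any() else np.sqrt(np.mean(phi**2))
    if rms > 0:
        phi = phi * (spec.phase_rms / rms)
    phi = phi * env

    peak = np.max(np.abs(phi))
    amp = np.ones_like(phi)
    if spec.amplitude_contrast != 0.0 and peak > 0:
        amp = np.clip(1.0 + spec.amplitude_contrast * phi / peak, 0.0, None)
    return ComplexField(
        amplitude=amp,
        phase=phi,
        wavelength_um=wavelength_um,
        pixel_um=spec.pixel_um,
        meta={"phantom": "fractal", "spec": asdict(spec), "seed": spec.seed},
    )


def knife_edge_forward(
    field_: ComplexField,
    background: float = 1.0,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> KnifeEdgeSet:
    """Forward knife-edge model: field → four half-blocked intensity images.

    With central-difference phase gradients g, the image pairs are
    Ix± = (B·A/2)(1 ± gain·g_x) and analogously in y, so both pair sums
    equal B·A exactly and the normalized differences return gain·g.
    |gain·g| is clipped just below 1 (count recorded in a module logger) to
    keep intensities nonnegative; optional additive Gaussian noise is
    clipped at zero.  Central (not spectral) differences make the forward
    model deliberately independent of the Fourier integrator.
    """
    if not (background > 0 and gain > 0 and noise_sd >= 0):
        raise ParameterError("background, gain must be > 0; noise_sd >= 0")
    phi = field_.phase
    gx = np.gradient(phi, axis=1)
    gy = np.gradient(phi, axis=0)
    tx = np.clip(gain * gx, -0.999, 0.999)
    ty = np.clip(gain * gy, -0.999, 0.999)
    base = background * field_.amplitude / 2.0
    ix_p = base * (1.0 + tx)
    ix_m = base * (1.0 - tx)
    iy_p = base * (1.0 + ty)
    iy_m = base * (1.0 - ty)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ix_p = np.clip(ix_p + rng.normal(0, noise_sd, phi.shape), 0, None)
        ix_m = np.clip(ix_m + rng.normal(0, noise_sd, phi.shape), 0, None)
        iy_p = np.clip(iy_p + rng.normal(0, noise_sd, phi.shape), 0, None)
        iy_m = np.clip(iy_m + rng.normal(0, noise_sd, phi.shape), 0, None)
    return KnifeEdgeSet(
        ix_plus=ix_p,
        ix_minus=ix_m,
        iy_plus=iy_p,
        iy_minus=iy_m,
        background=np.full(phi.shape, float(background)),
    )


@dataclass(frozen=True)
class ClassSpec:
    """One cohort class: per-feature mean shifts and SDs."""

    name: str
    shifts: tuple[float, ...]
    sds: tuple[float, ...] | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Labeled multi-class Gaussian cohort.

    Defaults mirror a three-subtype imaging-cytometry study: 17 features,
    2000 cells per class, unit SDs.
    """

    classes: tuple[ClassSpec, ...]
    n_per_class: int = 2000
    n_features: int = 17
    seed: int = 0
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ParameterError("need >= 2 classes")
        if self.n_per_class < 2:
            raise ParameterError("need n_per_class >= 2")
        for c in self.classes:
            if len(c.shifts) != self.n_features:
                raise ParameterError(
                    f"class {c.name!r}: {len(c.shifts)} shifts, expected {self.n_features}"
                )
            if c.sds is not None and len(c.sds) != self.n_features:
                raise ParameterError(f"class {c.name!r}: bad sds length")


def synth_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a labeled Gaussian cohort; deterministic given (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    names = list(spec.feature_names) if spec.feature_names else [
        f"f{i:02d}" for i in range(spec.n_features)
    ]
    blocks, labels, ids = [], [], []
    for c in spec.classes:
        sds = np.asarray(c.sds if c.sds is not None else np.ones(spec.n_features))
        block = rng.normal(
            loc=np.asarray(c.shifts), scale=sds, size=(spec.n_per_class, spec.n_features)
        )
        blocks.append(block)
        labels.extend([c.name] * spec.n_per_class)
        ids.extend(f"{c.name}_{i:05d}" for i in range(spec.n_per_class))
    return FeatureTable(
        values=np.vstack(blocks),
        feature_names=names,
        cell_ids=ids,
        labels=np.asarray(labels),
        meta={"seed": spec.seed, "n_per_class": spec.n_per_class},
    )
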