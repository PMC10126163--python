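"""Fourier-transform light scattering (FTLS) of a reconstructed field.

Instead of goniometric detection, the measured complex field ``E(x, y)`` is
numerically propagated to the far field with a Fourier transform,
``S(kx, ky) = F[E]``.  The squared modulus is the far-field scattering
pattern; averaging it over rings of constant scattering wave vector
``q = (4π/λ)·sin(θ/2)`` yields the angular light-scattering (ALS) profile.
The inverse transform of the pattern (Wiener–Khinchin theorem) is the
spatial autocorrelation of the field — the density–density correlation
curve ``C_ρ(r)`` whose log-log slope carries the fractal dimension.

Transform convention: unnormalized forward FFT, so Parseval reads
``Σ|E|² = Σ|S|² / N_pixels`` with ``N_pixels`` the (padded) grid size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, ParameterError, StructuralError
from .phase_field import ComplexField

__all__ = [
    "ScatteringPattern",
    "ALSProfile",
    "CorrelationCurve",
    "scattered_field",
    "far_field_pattern",
    "angular_profile",
    "density_correlation",
]


@dataclass
class ScatteringPattern:
    """2D far-field intensity |S(kx, ky)|² with centered frequency axes.

    Axes are in rad/μm, DC at the center bin (standard shifted-FFT layout;
    for even grid sizes the negative Nyquist bin has no positive partner).
    ``orig_shape`` is the unpadded field size, needed to bound correlation
    lags, and ``pixel_um`` the object-plane pitch.
    """

    intensity: np.ndarray
    kx_axis: np.ndarray
    ky_axis: np.ndarray
    wavelength_um: float
    pixel_um: float
    orig_shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise StructuralError("intensity must be 2D")
        if np.any(self.intensity < 0):
            raise StructuralError("intensity must be nonnegative")
        self.kx_axis = np.asarray(self.kx_axis, dtype=float)
        self.ky_axis = np.asarray(self.ky_axis, dtype=float)
        if (self.ky_axis.size, self.kx_axis.size) != self.intensity.shape:
            raise StructuralError("axes inconsistent with intensity shape")


@dataclass
class ALSProfile:
    """Ring-averaged angular light-scattering profile S(q).

    ``q`` (rad/μm) is strictly increasing with bin width one frequency
    pixel; ``theta`` are the matching polar scattering angles, related by
    q = (4π/λ)·sin(θ/2); ``counts`` is the number of pattern pixels per ring.
    """

    q: np.ndarray
    s: np.ndarray
    counts: np.ndarray
    theta: np.ndarray
    wavelength_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.counts = np.asarray(self.counts)
        self.theta = np.asarray(self.theta, dtype=float)
        if not (self.q.size == self.s.size == self.counts.size == self.theta.size):
            raise StructuralError("profile vectors must be aligned")
        if self.q.size and np.any(np.diff(self.q) <= 0):
            raise StructuralError("q must be strictly increasing")
        if np.any(self.s < 0):
            raise StructuralError("s must be nonnegative")


@dataclass
class CorrelationCurve:
    """Radially averaged field autocorrelation C(r) on positive lags.

    Normalized so the zero-lag value is 1; only strictly positive bins are
    retained so the curve is loggable.  ``log_r``/``log_c`` are natural logs.
    """

    r: np.ndarray
    c: np.ndarray
    pixel_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.r.size != self.c.size:
            raise StructuralError("r and c must be aligned")
        if self.r.size:
            if np.any(self.r <= 0) or np.any(np.diff(self.r) <= 0):
                raise StructuralError("r must be positive, strictly increasing")
            if np.any(self.c <= 0):
                raise StructuralError("retained c bins must be positive")

    @property
    def log_r(self) -> np.ndarray:
        return np.log(self.r)

    @property
    def log_c(self) -> np.ndarray:
        return np.log(self.c)


def scattered_field(field_: ComplexField, incident: complex = 1.0) -> ComplexField:
    """Scattered component of a field: E_s = E − E_incident.

    Subtracting the (unit plane-wave) incident field removes the DC-centered
    transform of the rectangular field of view, which otherwise swamps the
    small-angle scattering of a weak object — the standard preparation for
    comparing phantom ALS minima against analytic (Airy/Mie) patterns.
    """
    es = field_.field_values() - incident
    return ComplexField(
        amplitude=np.abs(es),
        phase=np.angle(es),
        wavelength_um=field_.wavelength_um,
        pixel_um=field_.pixel_um,
        meta={**field_.meta, "scattered_component": True},
    )


def far_field_pattern(
    field_: ComplexField, pad_factor: int = 1, window: str = "none"
) -> ScatteringPattern:
    """Propagate a complex field to the far field.

    The field ``A·exp(iφ)`` is optionally apodized with a 2D Hann window,
    zero-padded by ``pad_factor`` and transformed; the centered squared
    modulus is returned with frequency axes in rad/μm.
    """
    if int(pad_factor) < 1:
        raise ParameterError("pad_factor must be >= 1")
    if window not in ("none", "hann"):
        raise ParameterError(f"unknown window {window!r}")
    E = field_.field_values()
    if window == "hann":
        n0, n1 = E.shape
        E = E * np.outer(np.hanning(n0), np.hanning(n1))
    n0, n1 = E.shape
    m0, m1 = n0 * int(pad_factor), n1 * int(pad_factor)
    b0, b1 = (m0 - n0) // 2, (m1 - n1) // 2
    Ep = np.zeros((m0, m1), dtype=complex)
    Ep[b0 : b0 + n0, b1 : b1 + n1] = E
    S = np.fft.fftshift(np.fft.fft2(Ep))
    kx = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(m1, d=field_.pixel_um))
    ky = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(m0, d=field_.pixel_um))
    return ScatteringPattern(
        intensity=np.abs(S) ** 2,
        kx_axis=kx,
        ky_axis=ky,
        wavelength_um=field_.wavelength_um,
        pixel_um=field_.pixel_um,
        orig_shape=(n0, n1),
        meta={"pad_factor": int(pad_factor), "window": window},
    )


def angular_profile(p: ScatteringPattern) -> ALSProfile:
    """Ring-average a scattering pattern into an ALS profile.

    Each pixel's radial frequency ``k_r`` maps to a polar scattering angle
    via ``sinθ = k_r·λ/(2π)``; evanescent pixels (sinθ > 1) are discarded.
    Intensities are averaged in q bins one frequency-pixel wide; empty bins
    are dropped.
    """
    lam = p.wavelength_um
    if not lam > 0:
        raise ParameterError("wavelength_um must be positive")
    KX, KY = np.meshgrid(p.kx_axis, p.ky_axis)
    kr = np.hypot(KX, KY)
    sin_t = kr * lam / (2.0 * np.pi)
    prop = sin_t <= 1.0
    if not np.any(prop):
        raise DegenerateInputError("no propagating pixels in pattern")
    theta = np.arcsin(sin_t[prop])
    q = (4.0 * np.pi / lam) * np.sin(theta / 2.0)
    dkx = np.abs(np.diff(p.kx_axis)).min() if p.kx_axis.size > 1 else 1.0
    dky = np.abs(np.diff(p.ky_axis)).min() if p.ky_axis.size > 1 else 1.0
    dk = max(dkx, dky)
    idx = np.rint(q / dk).astype(int)
    nbins = idx.max() + 1
    sums = np.bincount(idx, weights=p.intensity[prop], minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    keep = counts >= 1
    centers = np.arange(nbins, dtype=float) * dk
    q_out = centers[keep]
    s_out = sums[keep] / counts[keep]
    theta_out = 2.0 * np.arcsin(np.clip(q_out * lam / (4.0 * np.pi), 0.0, 1.0))
    return ALSProfile(
        q=q_out,
        s=s_out,
        counts=counts[keep],
        theta=theta_out,
        wavelength_um=lam,
        meta={"bin_width": dk},
    )


def density_correlation(
    p: ScatteringPattern, mode: str = "wiener_khinchin_2d"
) -> CorrelationCurve:
    """Density-correlation curve from a scattering pattern.

    Wiener–Khinchin: the inverse 2D transform of |S|² is the (circular)
    spatial autocorrelation of the field on the image grid.  Its modulus is
    radially averaged over lag radius (bin width one pixel), normalized by
    the zero-lag value, and retained for lags between one pixel and half the
    unpadded field of view.  The modulus (not the real part) guarantees
    positivity for subsequent log-log fitting.
    """
    if mode != "wiener_khinchin_2d":
        raise ParameterError(f"unknown mode {mode!r}")
    ac = np.fft.ifft2(np.fft.ifftshift(p.intensity))
    mag = np.abs(ac)
    zero_lag = mag[0, 0]
    if zero_lag <= 0:
        raise DegenerateInputError("pattern carries no energy")
    mag = mag / zero_lag
    m0, m1 = mag.shape
    ly = np.minimum(np.arange(m0), m0 - np.arange(m0))[:, None]
    lx = np.minimum(np.arange(m1), m1 - np.arange(m1))[None, :]
    lag = np.hypot(ly, lx)
    idx = np.rint(lag).astype(int)
    nmax = min(p.orig_shape) // 2
    sel = (idx >= 1) & (idx <= nmax)
    sums = np.bincount(idx[sel], weights=mag[sel], minlength=nmax + 1)
    counts = np.bincount(idx[sel], minlength=nmax + 1)
    j = np.arange(nmax + 1)
    keep = (counts >= 1) & (j >= 1)
    c = np.zeros(nmax + 1)
    c[keep] = sums[keep] / counts[keep]
    keep &= c > 0
    return CorrelationCurve(
        r=j[keep] * p.pixel_um,
        c=c[keep],
        pixel_um=p.pixel_um,
        meta={"mode": mode, "zero_lag": float(zero_lag)},
    )
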