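"""Mie scattering series for a homogeneous sphere.

Exact plane-wave scattering by a sphere of size parameter x = 2π·n_med·R/λ
and relative refractive index m, used as the physics oracle for sphere
phantoms.  Scattering coefficients a_n, b_n are built from Riccati–Bessel
functions ψ_n(ρ) = ρ j_n(ρ) and ξ_n(ρ) = ρ (j_n(ρ) + i y_n(ρ)) evaluated
with scipy's spherical Bessel routines; the series is truncated at the
standard N = ⌈x + 4 x^{1/3} + 2⌉.  Valid for real m and x up to a few
hundred (upward evaluation of j_n(mx) is stable there).

Amplitude functions:
    S1(θ) = Σ (2n+1)/(n(n+1)) (a_n π_n + b_n τ_n)
    S2(θ) = Σ (2n+1)/(n(n+1)) (a_n τ_n + b_n π_n)
with the angular functions π_n, τ_n from their recurrence in cosθ.
Unpolarized intensity is (|S1|² + |S2|²)/2.
"""

from __future__ import annotations

import numpy as np
from scipy.special import spherical_jn, spherical_yn

from .exceptions import ParameterError

__all__ = ["mie_coefficients", "mie_S1_S2", "mie_intensity", "mie_efficiencies"]

X_MAX = 200.0


def _n_terms(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(m: float, x: float) -> tuple[np.ndarray, np.ndarray]:
    """Scattering coefficients (a_n, b_n), n = 1..N."""
    if not 0.0 < x <= X_MAX:
        raise ParameterError(f"size parameter x must be in (0, {X_MAX}], got {x}")
    N = _n_terms(x)
    n = np.arange(1, N + 1)
    mx = m * x

    jx = spherical_jn(n, x)
    jxd = spherical_jn(n, x, derivative=True)
    yx = spherical_yn(n, x)
    yxd = spherical_yn(n, x, derivative=True)
    jm = spherical_jn(n, mx)
    jmd = spherical_jn(n, mx, derivative=True)

    # Riccati-Bessel: psi(ρ) = ρ j_n(ρ)  =>  psi' = j_n + ρ j_n'
    psi_x = x * jx
    psi_x_d = jx + x * jxd
    psi_m = mx * jm
    psi_m_d = jm + mx * jmd
    xi_x = x * (jx + 1j * yx)
    xi_x_d = (jx + 1j * yx) + x * (jxd + 1j * yxd)

    a = (m * psi_m * psi_x_d - psi_x * psi_m_d) / (
        m * psi_m * xi_x_d - xi_x * psi_m_d
    )
    b = (psi_m * psi_x_d - m * psi_x * psi_m_d) / (
        psi_m * xi_x_d - m * xi_x * psi_m_d
    )
    return a, b


def _pi_tau(mu: np.ndarray, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Angular functions π_n(μ), τ_n(μ) for n = 1..N (rows)."""
    mu = np.asarray(mu, dtype=float)
    pi = np.zeros((N + 1, mu.size))
    tau = np.zeros((N + 1, mu.size))
    pi[1] = 1.0
    tau[1] = mu
    for n in range(2, N + 1):
        pi[n] = ((2 * n - 1) / (n - 1)) * mu * pi[n - 1] - (n / (n - 1)) * pi[n - 2]
        tau[n] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau[1:]


def mie_S1_S2(m: float, x: float, theta) -> tuple[np.ndarray, np.ndarray]:
    """Complex scattering amplitudes S1, S2 on a polar-angle grid (radians)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    a, b = mie_coefficients(m, x)
    N = a.size
    pi_n, tau_n = _pi_tau(np.cos(theta), N)
    n = np.arange(1, N + 1)[:, None]
    w = (2 * n + 1) / (n * (n + 1))
    S1 = np.sum(w * (a[:, None] * pi_n + b[:, None] * tau_n), axis=0)
    S2 = np.sum(w * (a[:, None] * tau_n + b[:, None] * pi_n), axis=0)
    return S1, S2


def mie_intensity(m: float, x: float, theta) -> np.ndarray:
    """Unpolarized scattered intensity (|S1|² + |S2|²)/2."""
    S1, S2 = mie_S1_S2(m, x, theta)
    return 0.5 * (np.abs(S1) ** 2 + np.abs(S2) ** 2)


def mie_efficiencies(m: float, x: float) -> tuple[float, float]:
    """Extinction and scattering efficiencies (Q_ext, Q_sca)."""
    a, b = mie_coefficients(m, x)
    n = np.arange(1, a.size + 1)
    qext = (2.0 / x**2) * float(np.sum((2 * n + 1) * (a.real + b.real)))
    qsca = (2.0 / x**2) * float(
        np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    )
    return qext, qsca
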