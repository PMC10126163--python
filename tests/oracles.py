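"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's FFT-based code paths: the spatial
autocorrelation is a literal shift-multiply-sum with periodic wrap, the
fractal-dimension fit runs on that oracle curve, Cliff's delta enumerates
all pairs, and the Mie coefficients come from the downward
logarithmic-derivative recurrence (the classic Bohren–Huffman scheme)
rather than direct spherical-Bessel evaluation.
"""

import numpy as np


def periodic_autocorr(E: np.ndarray) -> np.ndarray:
    """a[dy, dx] = sum_r E(r) conj(E(r + d)) with periodic wrap (O(N^4))."""
    n0, n1 = E.shape
    ac = np.zeros((n0, n1), dtype=complex)
    for dy in range(n0):
        for dx in range(n1):
            ac[dy, dx] = np.sum(E * np.conj(np.roll(np.roll(E, -dy, 0), -dx, 1)))
    return ac


def radial_curve(mag: np.ndarray, pixel_um: float, nmax: int):
    """Radially average an autocorrelation magnitude map into 1-pixel bins."""
    n0, n1 = mag.shape
    ly = np.minimum(np.arange(n0), n0 - np.arange(n0))[:, None]
    lx = np.minimum(np.arange(n1), n1 - np.arange(n1))[None, :]
    idx = np.rint(np.hypot(ly, lx)).astype(int)
    rs, cs = [], []
    for j in range(1, nmax + 1):
        sel = idx == j
        if sel.any():
            v = mag[sel].mean()
            if v > 0:
                rs.append(j * pixel_um)
                cs.append(v)
    return np.asarray(rs), np.asarray(cs)


def brute_force_fd(E: np.ndarray, pixel_um: float, r_lo: float, r_hi: float) -> float:
    """FD = 3 + slope of the log-log oracle autocorrelation over [r_lo, r_hi].

    Only lags within the fit range are evaluated (still a literal
    shift-multiply-sum, restricted for speed)."""
    n0, n1 = E.shape
    rmax = int(np.ceil(r_hi / pixel_um)) + 1
    ac0 = np.abs(np.sum(E * np.conj(E)))
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for dy in range(-rmax, rmax + 1):
        for dx in range(-rmax, rmax + 1):
            j = int(round(np.hypot(dx, dy)))
            if j < 1 or j > rmax:
                continue
            v = np.abs(np.sum(E * np.conj(np.roll(np.roll(E, -dy, 0), -dx, 1)))) / ac0
            sums[j] = sums.get(j, 0.0) + v
            counts[j] = counts.get(j, 0) + 1
    js = sorted(sums)
    r = np.array([j * pixel_um for j in js])
    c = np.array([sums[j] / counts[j] for j in js])
    sel = (r >= r_lo) & (r <= r_hi) & (c > 0)
    slope, _ = np.polyfit(np.log(r[sel]), np.log(c[sel]), 1)
    return 3.0 + slope


def cliffs_delta_enum(x, y) -> float:
    """Cliff's delta by full pair enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (x.size * y.size)


def bohren_huffman_mie(m: float, x: float):
    """Mie a_n, b_n via the downward log-derivative recurrence."""
    N = int(np.ceil(x + 4 * x ** (1.0 / 3.0) + 2))
    nmx = max(N, int(np.ceil(abs(m * x)))) + 16
    D = np.zeros(nmx + 1, dtype=complex)
    mx = m * x
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    a = np.zeros(N, complex)
    b = np.zeros(N, complex)
    pm, p = np.cos(x), np.sin(x)  # psi_{-1}, psi_0 by upward recurrence
    cm, c = -np.sin(x), np.cos(x)  # chi_{-1}, chi_0
    for n in range(1, N + 1):
        pn = (2 * n - 1) / x * p - pm
        cn = (2 * n - 1) / x * c - cm
        xi_prev = p - 1j * c
        xi_n = pn - 1j * cn
        da = D[n] / m + n / x
        db = D[n] * m + n / x
        a[n - 1] = (da * pn - p) / (da * xi_n - xi_prev)
        b[n - 1] = (db * pn - p) / (db * xi_n - xi_prev)
        pm, p = p, pn
        cm, c = c, cn
    return a, b
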