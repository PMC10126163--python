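"""Fractal-dimension estimation and the fractal/ALS feature catalog.

A mass-fractal object has a density–density correlation that decays as a
power law, ``C_ρ(r) ∝ r^(−α)``, over some range of length scales, and its
fractal dimension is ``FD = 3 − α``.  This module fits α by ordinary least
squares on the log-log correlation curve, detects the *fractal window* (FW)
— the contiguous range of correlation distances where the downward slope is
at least as steep as the overall fit, i.e. where power-law scaling actually
holds — refits the FD inside it, summarizes the ALS profile, and assembles
everything into a fixed, versioned 17-feature vector per cell.

All log-log fits use natural logarithms; window widths are reported in
decades (log10), the customary unit for scaling ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sp_stats

from .exceptions import InsufficientDataError, ParameterError
from .morphology import segment_cell
from .phase_field import ComplexField
from .scattering import (
    ALSProfile,
    CorrelationCurve,
    angular_profile,
    density_correlation,
    far_field_pattern,
    scattered_field,
)
from .exceptions import DegenerateInputError

__all__ = [
    "FractalFit",
    "FractalWindow",
    "FwConfig",
    "ProfileConfig",
    "FractalProfile",
    "FEATURE_NAMES",
    "CATALOG_VERSION",
    "fit_overall_fd",
    "detect_fractal_window",
    "fit_fd_within_window",
    "als_statistics",
    "fractal_profile",
]

#: Fixed, versioned order of the 17 fractal/ALS features.
FEATURE_NAMES: tuple[str, ...] = (
    "fd",
    "fd_mse2",
    "fd_with_fw",
    "fd_fw_mse",
    "fw_width",
    "fw_r_min",
    "fw_r_max",
    "fd_width",
    "fw_prominence",
    "als_log_mean",
    "als_log_sd",
    "als_log_skew",
    "als_log_kurt",
    "als_slope",
    "als_frac_lowq",
    "als_frac_midq",
    "als_frac_highq",
)
CATALOG_VERSION = "1"


@dataclass(frozen=True)
class FractalFit:
    """Power-law fit of a correlation curve: FD = 3 − α.

    ``alpha`` is the magnitude of the downward log-log slope, ``mse`` the
    mean squared residual of the linear fit in (natural) log-log space.
    """

    alpha: float
    mse: float
    r_lo: float
    r_hi: float
    n_bins: int

    @property
    def fd(self) -> float:
        return 3.0 - self.alpha

    @property
    def slope(self) -> float:
        """The signed log-log slope (−alpha)."""
        return -self.alpha


@dataclass(frozen=True)
class FractalWindow:
    """Detected interval [r_min, r_max] of power-law scaling.

    ``prominence`` integrates how much steeper the local slope is than the
    overall fit across the window; ``fallback`` marks curves where no
    eligible run met the minimum length and the whole analysis range was
    returned instead.
    """

    r_min: float
    r_max: float
    prominence: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ParameterError("fractal window requires r_min < r_max")

    @property
    def width_decades(self) -> float:
        return math.log10(self.r_max / self.r_min)


@dataclass(frozen=True)
class FwConfig:
    """Fractal-window detection settings.

    half_width
        Half-width w of the centered local-slope regression (2w+1 bins).
    min_bins / min_decades
        A candidate run must span at least ``min_bins`` bins *and*
        ``min_decades`` decades.
    """

    half_width: int = 2
    min_bins: int = 5
    min_decades: float = 0.3


def _select(curve: CorrelationCurve, r_lo, r_hi):
    r_lo = curve.r[0] if r_lo is None else float(r_lo)
    r_hi = curve.r[-1] if r_hi is None else float(r_hi)
    sel = (curve.r >= r_lo) & (curve.r <= r_hi)
    return sel, r_lo, r_hi


def fit_overall_fd(
    curve: CorrelationCurve, r_lo: float | None = None, r_hi: float | None = None
) -> FractalFit:
    """OLS fit of log C on log r over [r_lo, r_hi]; FD = 3 − α."""
    sel, r_lo, r_hi = _select(curve, r_lo, r_hi)
    n = int(sel.sum())
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 bins in [{r_lo:g}, {r_hi:g}], have {n}"
        )
    x = curve.log_r[sel]
    y = curve.log_c[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return FractalFit(
        alpha=float(-slope),
        mse=float(np.mean(resid**2)),
        r_lo=float(curve.r[sel][0]),
        r_hi=float(curve.r[sel][-1]),
        n_bins=n,
    )


def _local_slopes(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Centered (2w+1)-bin OLS slopes; windows truncate at the edges
    (minimum 3 bins) so boundary bins still receive a slope."""
    n = x.size
    s = np.empty(n)
    for i in range(n):
        lo = max(0, i - w)
        hi = min(n, i + w + 1)
        if hi - lo < 3:
            lo = max(0, min(lo, n - 3))
            hi = min(n, lo + 3)
        s[i] = np.polyfit(x[lo:hi], y[lo:hi], 1)[0]
    return s


def detect_fractal_window(
    curve: CorrelationCurve,
    overall: FractalFit,
    cfg: FwConfig | None = None,
    r_lo: float | None = None,
    r_hi: float | None = None,
) -> FractalWindow:
    """Find the most prominent downward-slope run of the correlation curve.

    Bins are *eligible* when their local log-log slope is at least as steep
    as the overall fit's (slope ≤ overall slope, equality included); short
    and long correlation-distance segments where linear scaling is weak fail
    this test and are excluded.  Among contiguous eligible runs meeting the
    minimum length, the one maximizing
    ``prominence = Σ (s_overall − s_local) · Δlog10 r`` wins; ties go to the
    longer run, then to the smaller r_min.  If no run qualifies, the whole
    analysis range is returned flagged as a fallback.
    """
    cfg = cfg or FwConfig()
    sel, _, _ = _select(curve, r_lo, r_hi)
    r = curve.r[sel]
    x = curve.log_r[sel]
    y = curve.log_c[sel]
    if r.size < 3:
        raise InsufficientDataError("need >= 3 bins for window detection")
    s_local = _local_slopes(x, y, int(cfg.half_width))
    s_over = overall.slope
    # closed under equality: a pure power law is eligible everywhere
    tol = 1e-12 * max(1.0, abs(s_over))
    eligible = s_local <= s_over + tol
    dlog10 = np.gradient(x) / math.log(10.0)

    runs = []
    i = 0
    n = r.size
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1

    best = None
    for i, j in runs:
        nb = j - i + 1
        width = math.log10(r[j] / r[i]) if r[j] > r[i] else 0.0
        if nb < cfg.min_bins or width < cfg.min_decades:
            continue
        prom = float(np.sum((s_over - s_local[i : j + 1]) * dlog10[i : j + 1]))
        key = (prom, nb, -r[i])
        if best is None or key > best[0]:
            best = (key, i, j, prom)
    if best is None:
        return FractalWindow(
            r_min=float(r[0]), r_max=float(r[-1]), prominence=0.0, fallback=True
        )
    _, i, j, prom = best
    return FractalWindow(r_min=float(r[i]), r_max=float(r[j]), prominence=prom)


def fit_fd_within_window(curve: CorrelationCurve, fw: FractalWindow) -> FractalFit:
    """Refit FD restricted to the detected fractal window."""
    return fit_overall_fd(curve, r_lo=fw.r_min, r_hi=fw.r_max)


def als_statistics(
    als: ALSProfile, q_cuts: tuple[float, float] | None = None
) -> dict[str, float]:
    """Eight summary statistics of an ALS profile.

    Computed over bins with q > 0 (the DC ring is excluded): mean, SD,
    skewness and excess kurtosis of log S; the OLS slope of log S vs log q;
    and the fractions of total scattered energy in the low/mid/high q bands
    split at ``q_cuts`` (default: 33rd/66th percentiles of the propagating q
    range — a parameter-free partition).
    """
    pos = als.q > 0
    q = als.q[pos]
    s = als.s[pos]
    if q.size < 8:
        raise InsufficientDataError("need >= 8 positive-q bins")
    floor = max(s.max(), np.finfo(float).tiny) * 1e-12
    ls = np.log(np.maximum(s, floor))
    lq = np.log(q)
    mean = float(ls.mean())
    # constant to machine precision: moments and slope are exactly zero
    if np.ptp(ls) < 1e-12 * max(1.0, abs(mean)):
        sd = 0.0
    else:
        sd = float(ls.std())
    if sd > 0:
        skew = float(sp_stats.skew(ls))
        kurt = float(sp_stats.kurtosis(ls))
        slope = float(np.polyfit(lq, ls, 1)[0])
    else:
        skew = kurt = slope = 0.0
    if q_cuts is None:
        q_cuts = tuple(np.percentile(q, [33.0, 66.0]))
    c1, c2 = q_cuts
    if not c1 < c2:
        raise ParameterError("q_cuts must be increasing")
    total = s.sum()
    total = total if total > 0 else 1.0
    low = float(s[q <= c1].sum() / total)
    mid = float(s[(q > c1) & (q <= c2)].sum() / total)
    high = float(s[q > c2].sum() / total)
    return {
        "als_log_mean": mean,
        "als_log_sd": sd,
        "als_log_skew": skew,
        "als_log_kurt": kurt,
        "als_slope": slope,
        "als_frac_lowq": low,
        "als_frac_midq": mid,
        "als_frac_highq": high,
    }


@dataclass(frozen=True)
class ProfileConfig:
    """End-to-end settings for per-cell fractal profiling."""

    pad_factor: int = 1
    window: str = "none"
    fw: FwConfig = field(default_factory=FwConfig)
    q_cuts: tuple[float, float] | None = None
    r_lo_um: float | None = None  # default: 2 × pixel pitch
    r_hi_um: float | None = None  # default: mask equivalent radius, else FOV/4
    segmentation: str = "otsu_phase"
    reset_background: bool = False
    #: analyze the scattered component E − 1 rather than the total field:
    #: the density fluctuation carries the fractal scaling, while the
    #: unscattered background only contributes the field-of-view window
    subtract_incident: bool = True


@dataclass(frozen=True)
class FractalProfile:
    """The 17-dimension fractal/ALS feature vector of one cell."""

    values: tuple[float, ...]
    degenerate: bool = False
    fw_fallback: bool = False
    catalog_version: str = CATALOG_VERSION

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ParameterError(
                f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}"
            )
        if not all(np.isfinite(self.values)):
            raise ParameterError("all features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def profile_from_curve_and_als(
    curve: CorrelationCurve,
    als: ALSProfile,
    cfg: ProfileConfig | None = None,
    r_lo: float | None = None,
    r_hi: float | None = None,
) -> FractalProfile:
    """Assemble the 17-feature vector from a correlation curve + ALS profile."""
    cfg = cfg or ProfileConfig()
    overall = fit_overall_fd(curve, r_lo=r_lo, r_hi=r_hi)
    degenerate = np.ptp(curve.log_c) < 1e-9
    fw = detect_fractal_window(curve, overall, cfg.fw, r_lo=r_lo, r_hi=r_hi)
    fw_fit = fit_fd_within_window(curve, fw)
    stats = als_statistics(als, q_cuts=cfg.q_cuts)
    vals = {
        "fd": overall.fd,
        "fd_mse2": overall.mse,
        "fd_with_fw": fw_fit.fd,
        "fd_fw_mse": fw_fit.mse,
        "fw_width": fw.width_decades,
        "fw_r_min": fw.r_min,
        "fw_r_max": fw.r_max,
        "fd_width": abs(overall.fd - fw_fit.fd),
        "fw_prominence": fw.prominence,
        **stats,
    }
    return FractalProfile(
        values=tuple(float(vals[name]) for name in FEATURE_NAMES),
        degenerate=bool(degenerate),
        fw_fallback=fw.fallback,
    )


def fractal_profile(
    field_: ComplexField, cfg: ProfileConfig | None = None
) -> FractalProfile:
    """Full per-cell pipeline: FTLS → ALS → C_ρ(r) → fits → 17 features.

    The analysis range defaults to [2 × pixel pitch, equivalent cell radius]
    — the lower bound keeps the fit inside the resolved scales, the upper
    bound inside the cell; if segmentation degenerates (e.g. a uniform
    field) a quarter of the field of view is used instead.
    """
    cfg = cfg or ProfileConfig()
    mask = None
    if cfg.reset_background or cfg.r_hi_um is None:
        try:
            mask = segment_cell(field_, method=cfg.segmentation)
        except DegenerateInputError:
            mask = None
    if cfg.reset_background and mask is not None:
        amp = field_.amplitude.copy()
        phi = field_.phase.copy()
        amp[~mask.mask] = 1.0
        phi[~mask.mask] = 0.0
        field_ = replace(field_, amplitude=amp, phase=phi)
    analysis_field = scattered_field(field_) if cfg.subtract_incident else field_
    if not np.any(analysis_field.amplitude > 0):
        # featureless scene: the scattered component vanishes; analyze the
        # total field (flat correlation, FD = 3, flagged degenerate below)
        analysis_field = field_
    pattern = far_field_pattern(
        analysis_field, pad_factor=cfg.pad_factor, window=cfg.window
    )
    als = angular_profile(pattern)
    curve = density_correlation(pattern)
    r_lo = cfg.r_lo_um if cfg.r_lo_um is not None else 2.0 * field_.pixel_um
    if cfg.r_hi_um is not None:
        r_hi = cfg.r_hi_um
    elif mask is not None:
        r_hi = mask.equivalent_radius_um
    else:
        r_hi = 0.25 * min(field_.shape) * field_.pixel_um
    r_hi = max(r_hi, curve.r[min(4, curve.r.size - 1)])  # keep >= 3 usable bins
    return profile_from_curve_and_als(curve, als, cfg, r_lo=r_lo, r_hi=r_hi)
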