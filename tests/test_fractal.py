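import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fractometry as fm
from fractometry.exceptions import InsufficientDataError
from fractometry.fractal import FEATURE_NAMES, profile_from_curve_and_als
from fractometry.scattering import scattered_field


def power_law_curve(alpha, k=1.0, n=50, r0=0.1, r1=10.0):
    r = np.logspace(np.log10(r0), np.log10(r1), n)
    return fm.CorrelationCurve(r=r, c=k * r ** (-alpha), pixel_um=0.1)


def piecewise_curve(bins_per_decade=20):
    """flat for r < 1, slope −1 for 1 ≤ r ≤ 10, flat beyond."""
    r = np.logspace(-1, 2, 3 * bins_per_decade + 1)
    lr = np.log10(r)
    logc = np.where(lr < 0, 0.0, np.where(lr <= 1, -lr, -1.0))
    return fm.CorrelationCurve(r=r, c=10.0**logc, pixel_um=0.1)


class TestOverallFit:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.5, 3.0])
    @pytest.mark.parametrize("k", [1.0, 0.37, 120.0])
    def test_fd_identity_on_injected_power_laws(self, alpha, k):
        fit = fm.fit_overall_fd(power_law_curve(alpha, k))
        assert fit.fd == pytest.approx(3.0 - alpha, abs=1e-12)
        assert fit.mse == pytest.approx(0.0, abs=1e-24)

    def test_flat_curve_fd_three(self):
        fit = fm.fit_overall_fd(power_law_curve(0.0, 2.0))
        assert fit.fd == pytest.approx(3.0, abs=1e-12)

    def test_mse_closed_form_with_orthogonal_residuals(self):
        # +0.1/−0.1 residual blocks (+,−,−,+) are orthogonal to the linear
        # trend on an equally spaced log grid, so the OLS line is unchanged
        # and mse = 0.1² exactly
        n = 48
        r = np.logspace(-1, 1, n)
        block = np.array([1.0, -1.0, -1.0, 1.0])
        resid = 0.1 * np.tile(block, n // 4)
        c = r**-0.5 * np.exp(resid)
        fit = fm.fit_overall_fd(fm.CorrelationCurve(r=r, c=c, pixel_um=0.1))
        assert fit.mse == pytest.approx(0.01, abs=1e-12)
        assert fit.alpha == pytest.approx(0.5, abs=1e-12)

    def test_insufficient_bins_raise(self):
        curve = power_law_curve(0.5)
        with pytest.raises(InsufficientDataError):
            fm.fit_overall_fd(curve, r_lo=0.1, r_hi=0.11)

    def test_scale_equivariance(self):
        c1 = power_law_curve(0.7, k=1.0)
        c2 = fm.CorrelationCurve(r=c1.r * 3.0, c=5.0 * c1.c, pixel_um=0.1)
        f1, f2 = fm.fit_overall_fd(c1), fm.fit_overall_fd(c2)
        assert f2.fd == pytest.approx(f1.fd, abs=1e-12)
        assert f2.mse == pytest.approx(f1.mse, abs=1e-20)


class TestFractalWindow:
    def test_pure_power_law_spans_full_range(self):
        curve = power_law_curve(1.0)
        fw = fm.detect_fractal_window(curve, fm.fit_overall_fd(curve))
        assert fw.r_min == curve.r[0] and fw.r_max == curve.r[-1]
        assert not fw.fallback

    def test_piecewise_breakpoints_within_one_bin(self):
        curve = piecewise_curve()
        overall = fm.fit_overall_fd(curve)
        fw = fm.detect_fractal_window(curve, overall)
        bin_step = 1.0 / 20  # decades per bin
        assert abs(np.log10(fw.r_min) - 0.0) <= bin_step + 1e-12
        assert abs(np.log10(fw.r_max) - 1.0) <= bin_step + 1e-12

    def test_longer_of_two_equal_steepness_segments_wins(self):
        r = np.logspace(-1, 2.4, 71)

        def logc(x):
            if x < 0:
                return 0.0
            if x <= 0.5:
                return -x  # short steep segment, 0.5 decades
            if x < 1.2:
                return -0.5
            if x <= 2.2:
                return -0.5 - (x - 1.2)  # long steep segment, 1 decade
            return -1.5

        curve = fm.CorrelationCurve(
            r=r, c=10.0 ** np.array([logc(x) for x in np.log10(r)]), pixel_um=0.1
        )
        fw = fm.detect_fractal_window(curve, fm.fit_overall_fd(curve))
        assert 1.1 <= np.log10(fw.r_min) <= 1.3
        assert 2.1 <= np.log10(fw.r_max) <= 2.3

    def test_no_eligible_run_returns_flagged_fallback(self):
        # strongly convex curve with a tiny steep stretch below min length
        r = np.logspace(-1, 1, 9)
        c = np.exp(-((np.log10(r)) ** 2))
        curve = fm.CorrelationCurve(r=r, c=c, pixel_um=0.1)
        fw = fm.detect_fractal_window(
            curve, fm.fit_overall_fd(curve), fm.FwConfig(min_bins=9, min_decades=2.1)
        )
        assert fw.fallback
        assert fw.r_min == curve.r[0] and fw.r_max == curve.r[-1]

    def test_fd_within_window_on_piecewise_curve(self):
        curve = piecewise_curve()
        overall = fm.fit_overall_fd(curve)
        fw = fm.detect_fractal_window(curve, overall)
        fit = fm.fit_fd_within_window(curve, fw)
        assert fit.fd == pytest.approx(2.0, abs=0.02)

    def test_fallback_fit_equals_overall(self):
        curve = power_law_curve(0.8)
        overall = fm.fit_overall_fd(curve)
        fw = fm.FractalWindow(r_min=curve.r[0], r_max=curve.r[-1], prominence=0.0, fallback=True)
        fit = fm.fit_fd_within_window(curve, fw)
        assert fit.fd == pytest.approx(overall.fd, abs=1e-12)

    def test_rescaling_r_shifts_window_leaves_fd(self):
        curve = piecewise_curve()
        overall = fm.fit_overall_fd(curve)
        fw1 = fm.detect_fractal_window(curve, overall)
        gamma = 4.0
        curve2 = fm.CorrelationCurve(r=curve.r * gamma, c=curve.c, pixel_um=0.1)
        overall2 = fm.fit_overall_fd(curve2)
        fw2 = fm.detect_fractal_window(curve2, overall2)
        assert fw2.r_min == pytest.approx(gamma * fw1.r_min, rel=1e-9)
        assert fw2.r_max == pytest.approx(gamma * fw1.r_max, rel=1e-9)
        assert fw2.width_decades == pytest.approx(fw1.width_decades, abs=1e-9)
        assert overall2.fd == pytest.approx(overall.fd, abs=1e-12)


class TestAlsStatistics:
    def make_profile(self, q, s):
        return fm.ALSProfile(
            q=q, s=s, counts=np.ones_like(q, int),
            theta=2 * np.arcsin(np.clip(q * 1.064 / (4 * np.pi), 0, 1)),
            wavelength_um=1.064,
        )

    def test_constant_profile_zero_moments_and_slope(self):
        q = np.linspace(0.1, 5, 20)
        stats = fm.als_statistics(self.make_profile(q, np.full(20, 2.5)))
        for key in ("als_log_sd", "als_log_skew", "als_log_kurt", "als_slope"):
            assert stats[key] == 0.0

    def test_power_law_profile_slope(self):
        q = np.logspace(-1, 1, 30)
        stats = fm.als_statistics(self.make_profile(q, q**-2.0))
        assert stats["als_slope"] == pytest.approx(-2.0, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_band_fractions_partition_unity(self, seed):
        r = np.random.default_rng(seed)
        q = np.sort(r.uniform(0.01, 10, 24))
        q += np.arange(24) * 1e-6  # strictly increasing
        s = r.uniform(0.1, 5.0, 24)
        stats = fm.als_statistics(self.make_profile(q, s))
        total = stats["als_frac_lowq"] + stats["als_frac_midq"] + stats["als_frac_highq"]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_too_few_bins_raise(self):
        q = np.linspace(0.1, 1, 5)
        with pytest.raises(InsufficientDataError):
            fm.als_statistics(self.make_profile(q, np.ones(5)))


class TestFractalProfile:
    def test_emits_exactly_17_features(self, sphere_field):
        prof = fm.fractal_profile(sphere_field)
        assert len(prof.values) == 17
        assert len(FEATURE_NAMES) == 17
        assert all(np.isfinite(prof.values))

    def test_uniform_field_degenerate_flag_and_fd_three(self):
        f = fm.ComplexField(
            amplitude=np.ones((64, 64)), phase=np.zeros((64, 64)),
            wavelength_um=1.064, pixel_um=0.2,
        )
        prof = fm.fractal_profile(f)
        assert prof.degenerate
        assert prof.as_dict()["fd"] == pytest.approx(3.0, abs=1e-9)

    def test_feature_order_fixed(self, sphere_field):
        prof = fm.fractal_profile(sphere_field)
        assert list(prof.as_dict().keys()) == list(FEATURE_NAMES)

    def test_fd_monotone_in_spectral_exponent(self):
        means = []
        for beta in (1.0, 2.0, 3.0):
            fds = []
            for seed in range(5):
                f = fm.fractal_phantom(fm.FractalFieldSpec(
                    beta=beta, grid_size=128, seed=seed,
                    phase_rms=0.1, envelope_radius_um=12.8,
                ))
                curve = fm.density_correlation(
                    fm.far_field_pattern(scattered_field(f))
                )
                fds.append(fm.fit_overall_fd(curve, r_lo=0.4, r_hi=1.6).fd)
            means.append(np.mean(fds))
        assert means[0] < means[1] < means[2]

    def test_profile_from_injected_curve(self):
        curve = piecewise_curve()
        q = np.logspace(-1, 1, 30)
        als = fm.ALSProfile(
            q=q, s=q**-1.5, counts=np.ones(30, int),
            theta=2 * np.arcsin(np.clip(q * 1.064 / (4 * np.pi), 0, 1)),
            wavelength_um=1.064,
        )
        prof = profile_from_curve_and_als(curve, als)
        d = prof.as_dict()
        assert d["fd_with_fw"] == pytest.approx(2.0, abs=0.02)
        assert d["fd_width"] == pytest.approx(abs(d["fd"] - d["fd_with_fw"]), abs=1e-12)
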