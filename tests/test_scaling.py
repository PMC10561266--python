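"""Scaled-Coulomb fitting, scaling-factor extraction, block bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionscreen.constants import COULOMB_CONSTANT
from ionscreen.decompose import CoulombProfile
from ionscreen.scaling import (
    ScaledCoulombModel,
    bootstrap_scaling_error,
    extract_scaling_factor,
    fit_scaled_coulomb,
)
from ionscreen.windows import MeanForceWindow

GRID = np.round(np.linspace(3.0, 10.0, 20), 6)


def profile_from(fn, grid=GRID, sigma=None):
    return CoulombProfile(grid, fn(grid), sigma=sigma)


class TestTwoRegionFit:
    def test_exact_linear_model_recovered_in_both_regions(self):
        prof = profile_from(lambda r: 1000.0 / r + 5.0)
        short, long_ = fit_scaled_coulomb(prof, boundary=6.5)
        for fit in (short, long_):
            assert fit.slope_a == pytest.approx(1000.0, rel=1e-10)
            assert fit.intercept_b == pytest.approx(5.0, rel=1e-8)
            assert fit.residual_rms < 1e-10

    def test_screened_coulomb_slope(self):
        prof = profile_from(lambda r: 0.81**2 * COULOMB_CONSTANT / r)
        short, long_ = fit_scaled_coulomb(prof)
        assert short.slope_a == pytest.approx(911.6, abs=0.1)
        assert long_.slope_a == pytest.approx(911.6, abs=0.1)

    def test_noisy_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(5)
        a_true = 0.81**2 * COULOMB_CONSTANT
        prof = profile_from(lambda r: a_true / r + rng.normal(0, 1.0, len(r)))
        short, long_ = fit_scaled_coulomb(prof)
        for fit in (short, long_):
            assert abs(fit.slope_a - a_true) < 3 * fit.slope_stderr

    def test_boundary_point_belongs_to_short_region(self):
        grid = np.array([3.0, 4.0, 5.0, 6.5, 7.0, 8.0, 9.0])
        prof = CoulombProfile(grid, 1.0 / grid)
        short, long_ = fit_scaled_coulomb(prof, boundary=6.5)
        assert short.n_points == 4
        assert long_.n_points == 3
        assert short.region[1] == 6.5

    def test_region_split_roughly_balanced_on_study_grid(self):
        short, long_ = fit_scaled_coulomb(profile_from(lambda r: 1.0 / r))
        assert abs(short.n_points - long_.n_points) <= len(GRID) // 3

    def test_sparse_region_rejected(self):
        grid = np.array([3.0, 4.0, 5.0, 6.0])
        prof = CoulombProfile(grid, 1.0 / grid)
        with pytest.raises(ValueError, match="long"):
            fit_scaled_coulomb(prof, boundary=6.5)


class TestExtractScalingFactor:
    def test_unscreened_vacuum(self):
        prof = profile_from(lambda r: COULOMB_CONSTANT / r)
        short, _ = fit_scaled_coulomb(prof)
        assert extract_scaling_factor(short, 1.0, 1.0).s == pytest.approx(1.0, abs=1e-10)

    def test_perfect_square_slopes(self):
        prof = profile_from(lambda r: 0.5625 * COULOMB_CONSTANT / r)
        _, long_ = fit_scaled_coulomb(prof)
        # like negative charges are equivalent to like positive ones
        assert extract_scaling_factor(long_, -1.0, -1.0).s == pytest.approx(0.75, abs=1e-10)

    def test_unlike_charges_rejected(self):
        prof = profile_from(lambda r: COULOMB_CONSTANT / r)
        short, _ = fit_scaled_coulomb(prof)
        with pytest.raises(ValueError, match="alike"):
            extract_scaling_factor(short, 1.0, -1.0)

    def test_attractive_fit_rejected(self):
        prof = profile_from(lambda r: -100.0 / r)
        short, _ = fit_scaled_coulomb(prof)
        with pytest.raises(ValueError, match="slope"):
            extract_scaling_factor(short, 1.0, 1.0)

    @given(st.floats(0.05, 1.0))
    @settings(derandomize=True, max_examples=60)
    def test_generation_fit_round_trip(self, s):
        """U_C = s²·k_C/r + b fitted back gives s to 1e-12 (noise-free)."""
        prof = profile_from(lambda r: s**2 * COULOMB_CONSTANT / r - 7.0)
        short, long_ = fit_scaled_coulomb(prof)
        for fit in (short, long_):
            assert extract_scaling_factor(fit, 1.0, 1.0).s == pytest.approx(
                s, rel=1e-12
            )

    def test_monotone_in_screening_strength(self):
        fitted = []
        for eps in (1.0, 1.2, 1.52, 1.78, 2.2):
            s_true = eps**-0.5
            prof = profile_from(lambda r: s_true**2 * COULOMB_CONSTANT / r)
            _, long_ = fit_scaled_coulomb(prof)
            fitted.append(extract_scaling_factor(long_, 1.0, 1.0).s)
        assert all(b < a for a, b in zip(fitted, fitted[1:]))


def synth_windows(grid, force_fn, noise, n, rng, dt=2.0):
    out = []
    for r in grid:
        series = force_fn(r) + noise * rng.standard_normal(n)
        out.append(MeanForceWindow(r, series, dt, n, 0))
    return out


class TestBootstrap:
    def test_constant_forces_give_zero_stderr(self):
        grid = np.linspace(3, 9, 8)
        cw = synth_windows(grid, lambda r: COULOMB_CONSTANT / r**2, 0.0, 1200,
                           np.random.default_rng(0))
        zw = synth_windows(grid, lambda r: 0.0, 0.0, 1200, np.random.default_rng(1))
        out = bootstrap_scaling_error(cw, zw, n_resamples=150, seed=3, boundary=6.0)
        assert out["long"].stderr < 1e-12  # zero up to floating-point noise
        assert out["short"].stderr < 1e-12

    def test_seed_determinism(self):
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(8)
        grid = np.linspace(3, 9, 8)
        cw = synth_windows(grid, lambda r: COULOMB_CONSTANT / r**2, 15.0, 1500, rng1)
        zw = synth_windows(grid, lambda r: 0.0, 15.0, 1500, rng2)
        a = bootstrap_scaling_error(cw, zw, n_resamples=150, seed=11, boundary=6.0)
        b = bootstrap_scaling_error(cw, zw, n_resamples=150, seed=11, boundary=6.0)
        assert a["long"].stderr == b["long"].stderr
        assert a["long"].s == b["long"].s

    def test_stderr_matches_delta_method_on_iid_noise(self):
        """For i.i.d. block noise the bootstrap error must agree with the
        error propagated analytically through the linear chain within 1.5x."""
        rng = np.random.default_rng(21)
        grid = np.linspace(3.0, 9.0, 10)
        noise, n = 20.0, 3000
        cw = synth_windows(grid, lambda r: COULOMB_CONSTANT / r**2, noise, n, rng)
        zw = synth_windows(grid, lambda r: 0.0, noise, n, rng)
        out = bootstrap_scaling_error(cw, zw, n_resamples=400, seed=2, boundary=6.0)

        # delta method: var of each window mean -> TI weights -> subtraction
        # -> OLS slope weights -> ds/da
        var_mean = noise**2 / n
        # TI weight of window j in F(r_k): from the trapezoid rule
        m = len(grid)
        dr = np.diff(grid)
        W = np.zeros((m, m))
        for k in range(m - 1):
            for j in range(m):
                w = 0.0
                if k <= j <= m - 2:
                    w += 0.5 * dr[j]
                if j >= k + 1:
                    w += 0.5 * dr[j - 1]
                W[k, j] = w
        cov_f = (W * var_mean) @ W.T * 2.0  # charged + zerocharge windows
        x = 1.0 / grid
        mask = grid > 6.0
        xm = x[mask] - x[mask].mean()
        c = np.zeros(m)
        c[mask] = xm / (xm @ xm)
        var_a = c @ cov_f @ c
        a_true = COULOMB_CONSTANT
        sd_s = np.sqrt(var_a) / (2 * np.sqrt(a_true * COULOMB_CONSTANT))
        ratio = out["long"].stderr / (1.96 * sd_s)
        assert 1 / 1.5 < ratio < 1.5

    def test_excessive_failures_raise(self):
        grid = np.linspace(3, 9, 8)
        rng = np.random.default_rng(0)
        # forces so noisy the fitted slope frequently turns negative
        cw = synth_windows(grid, lambda r: 0.0, 500.0, 200, rng)
        zw = synth_windows(grid, lambda r: 0.0, 500.0, 200, rng)
        with pytest.raises((RuntimeError, ValueError)):
            bootstrap_scaling_error(cw, zw, n_resamples=150, seed=5, boundary=6.0)

    def test_minimum_resamples_enforced(self):
        with pytest.raises(ValueError, match="resamples"):
            bootstrap_scaling_error([], [], n_resamples=10, seed=0)


class TestModelInterface:
    def test_fit_and_summary(self):
        prof = profile_from(lambda r: 0.6561 * COULOMB_CONSTANT / r + 3.0)
        res = ScaledCoulombModel(prof, charges=(1, 1)).fit()
        assert res.s_short == pytest.approx(0.81, abs=1e-10)
        assert res.s_long == pytest.approx(0.81, abs=1e-10)
        text = res.summary()
        assert "short" in text and "long" in text and "0.810" in text

    def test_unlike_charges_rejected_at_construction(self):
        prof = profile_from(lambda r: 1.0 / r)
        with pytest.raises(ValueError, match="like"):
            ScaledCoulombModel(prof, charges=(1, -1))

    def test_predicted_matches_exact_line(self):
        prof = profile_from(lambda r: 900.0 / r + 1.0)
        res = ScaledCoulombModel(prof).fit()
        assert np.allclose(res.predicted("long"), prof.coulomb_energy, atol=1e-8)
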