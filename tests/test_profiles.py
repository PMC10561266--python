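"""Mean forces, thermodynamic integration, volume-entropy correction."""

import numpy as np
import pytest

from ionscreen.constants import BOLTZMANN_KJ_MOL_K, COULOMB_CONSTANT
from ionscreen.profiles import (
    FreeEnergyProfile,
    add_entropy_correction,
    integrate_mean_force,
    window_mean_force,
)
from ionscreen.windows import MeanForceWindow


def make_window(series, r=5.0, dt=2.0):
    series = np.asarray(series, dtype=float)
    return MeanForceWindow(r, series, dt, len(series), 0)


class TestWindowMeanForce:
    def test_constant_series(self):
        mean, err = window_mean_force(make_window(np.full(1000, 3.25)))
        assert mean == 3.25
        assert err == 0.0

    def test_alternating_series_cancels_blockwise(self):
        series = np.tile([1.0, -1.0], 500)
        mean, err = window_mean_force(make_window(series), block_fs=4.0)
        assert mean == 0.0
        assert err == 0.0

    def test_iid_gaussian_standard_error(self):
        rng = np.random.default_rng(0)
        series = rng.normal(2.0, 1.0, 1000)
        mean, err = window_mean_force(make_window(series), block_fs=20.0)
        assert mean == pytest.approx(2.0, abs=0.1)
        assert 1 / np.sqrt(1000) / 1.5 < err < 1.5 / np.sqrt(1000)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError, match="two blocks"):
            window_mean_force(make_window(np.ones(100)), block_fs=1000.0)

    def test_block_shorter_than_timestep_rejected(self):
        with pytest.raises(ValueError, match="block"):
            window_mean_force(make_window(np.ones(100)), block_fs=0.5)


class TestIntegrateMeanForce:
    def test_constant_force_gives_linear_profile(self):
        f = 2.5
        windows = [(r, f, 0.0) for r in np.linspace(3, 10, 8)]
        prof = integrate_mean_force(windows)
        assert np.allclose(prof.free_energy, f * (10.0 - prof.distances))
        assert np.allclose(prof.sigma, 0.0)

    def test_inverse_square_force_recovers_coulomb(self):
        grid = np.arange(3.0, 10.01, 0.25)
        windows = [(r, COULOMB_CONSTANT / r**2, 0.0) for r in grid]
        prof = integrate_mean_force(windows)
        expected = COULOMB_CONSTANT * (1 / 3.0 - 1 / 10.0)  # 324.2 kJ/mol
        assert prof.free_energy[0] - prof.free_energy[-1] == pytest.approx(
            expected, rel=0.01
        )

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        windows = [(r, rng.normal(), 0.1) for r in np.linspace(3, 9, 7)]
        a = integrate_mean_force(windows)
        b = integrate_mean_force(windows[::-1])
        assert np.array_equal(a.free_energy, b.free_energy)
        assert np.array_equal(a.sigma, b.sigma)

    def test_quadratic_convergence_on_smooth_force(self):
        # trapezoid error must shrink ~4x when the spacing is halved
        def err(h):
            grid = np.arange(3.0, 9.0 + h / 2, h)
            windows = [(r, COULOMB_CONSTANT / r**2, 0.0) for r in grid]
            prof = integrate_mean_force(windows)
            exact = COULOMB_CONSTANT * (1 / prof.distances - 1 / 9.0)
            return np.max(np.abs(prof.free_energy - exact))

        ratio = err(0.5) / err(0.25)
        assert 3.0 < ratio < 5.0

    def test_duplicate_distances_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            integrate_mean_force([(3.0, 1.0, 0.0), (3.0, 2.0, 0.0), (4.0, 1.0, 0.0)])

    def test_missing_force_rejected(self):
        with pytest.raises(ValueError, match="force"):
            integrate_mean_force([(3.0, np.nan, 0.0), (4.0, 1.0, 0.0)])

    def test_sigma_propagation_through_trapezoid_weights(self):
        # two windows: F(r0) = 0.5*dr*(f0+f1); σ² = (0.5 dr σ0)² + (0.5 dr σ1)²
        windows = [(3.0, 1.0, 0.2), (5.0, 1.0, 0.4)]
        prof = integrate_mean_force(windows)
        assert prof.sigma[0] == pytest.approx(np.hypot(1.0 * 0.2, 1.0 * 0.4))
        assert prof.sigma[1] == 0.0


class TestEntropyCorrection:
    def test_doubling_distance_value(self):
        prof = FreeEnergyProfile(np.array([2.0, 4.0]), np.zeros(2), reference="rmin")
        out = add_entropy_correction(prof, 300.0)
        # 2 k_B T ln 2 at twice the reference distance
        assert out.free_energy[1] == pytest.approx(
            2 * BOLTZMANN_KJ_MOL_K * 300.0 * np.log(2.0), rel=1e-12
        )
        assert out.free_energy[0] == 0.0

    def test_reference_point_unchanged(self):
        prof = FreeEnergyProfile(np.linspace(3, 9, 5), np.linspace(5, 0, 5))
        out = add_entropy_correction(prof, 300.0)
        assert out.free_energy[-1] == prof.free_energy[-1]

    def test_double_application_guarded(self):
        prof = FreeEnergyProfile(np.linspace(3, 9, 5), np.zeros(5))
        once = add_entropy_correction(prof, 300.0)
        with pytest.raises(ValueError, match="already"):
            add_entropy_correction(once, 300.0)


class TestProfileValidation:
    def test_non_monotonic_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            FreeEnergyProfile(np.array([3.0, 2.0, 4.0]), np.zeros(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            FreeEnergyProfile(np.array([3.0, 4.0]), np.zeros(3))


def test_full_chain_recovers_screened_coulomb():
    """Noisy screened-Coulomb windows integrate back to
    s²·k_C/r + 2kT·ln(r/r_ref) within the propagated uncertainty."""
    rng = np.random.default_rng(42)
    s2 = 0.66
    grid = np.linspace(3.0, 9.0, 13)
    n = 2000
    windows = []
    for r in grid:
        series = s2 * COULOMB_CONSTANT / r**2 + rng.normal(0, 10.0, n)
        w = MeanForceWindow(r, series, 2.0, n, 0)
        windows.append((r, *window_mean_force(w, block_fs=100.0)))
    prof = add_entropy_correction(integrate_mean_force(windows, 300.0), 300.0)
    # reference: the same chain on the noiseless forces, so the comparison
    # isolates the statistical error from the trapezoid discretization bias
    noiseless = [(r, s2 * COULOMB_CONSTANT / r**2, 0.0) for r in grid]
    ref = add_entropy_correction(integrate_mean_force(noiseless, 300.0), 300.0)
    resid = np.abs(prof.free_energy - ref.free_energy)
    tol = 4 * np.maximum(prof.sigma, 0.05)  # sigma is 0 at the anchor point
    assert np.all(resid[:-1] < tol[:-1])
    # and the analytic target is still matched within noise + O(h²) bias
    kt2 = 2 * BOLTZMANN_KJ_MOL_K * 300.0
    exact = s2 * COULOMB_CONSTANT * (1 / grid - 1 / grid[-1]) + kt2 * np.log(grid / grid[-1])
    assert np.max(np.abs(ref.free_energy - exact)) < 0.01 * np.max(np.abs(exact))
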