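import itertools

import numpy as np
import pytest

from t2pools import (
    FitConfig,
    SequenceParams,
    T2Grid,
    build_decay_basis,
    epg_echo_amplitudes,
)
from t2pools.compartment_maps import CompartmentBoundaries, compartmentalize
from t2pools.spectrum_fit import (
    T2Spectrum,
    estimate_flip_angle,
    fit_volume,
    fit_voxel,
    nnls_solve,
    regularized_nnls,
)


def kkt_satisfied(basis, signal, x, rtol=1e-8):
    """KKT certificate for min ||Ax-b||^2, x>=0."""
    grad = basis.T @ (basis @ x - signal)
    scale = max(np.abs(grad).max(), 1.0)
    active = x > 0
    return np.all(grad[~active] >= -rtol * scale) and np.all(
        np.abs(grad[active]) <= rtol * scale
    )


def brute_force_nnls(basis, signal):
    """Exhaustive search over all active sets (small problems only)."""
    n = basis.shape[1]
    best_x, best_obj = np.zeros(n), float(signal @ signal)
    for r in range(1, n + 1):
        for support in itertools.combinations(range(n), r):
            sub = basis[:, support]
            coef, *_ = np.linalg.lstsq(sub, signal, rcond=None)
            if np.any(coef < -1e-12):
                continue
            x = np.zeros(n)
            x[list(support)] = np.clip(coef, 0.0, None)
            resid = basis @ x - signal
            obj = float(resid @ resid)
            if obj < best_obj - 1e-12:
                best_obj, best_x = obj, x
    return best_x, best_obj


def three_pool_signal(alpha, pools, params):
    return sum(f * epg_echo_amplitudes(t2, params.with_flip(alpha)) for f, t2 in pools)


class TestNnlsSolve:
    def test_identity_passthrough(self):
        np.testing.assert_allclose(nnls_solve(np.eye(3), np.array([2.0, 0.0, 5.0])), [2, 0, 5])

    def test_negative_component_clipped(self):
        np.testing.assert_allclose(nnls_solve(np.eye(2), np.array([3.0, -1.0])), [3, 0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nnls_solve(np.eye(3), np.zeros(2))

    def test_zero_signal(self):
        np.testing.assert_array_equal(nnls_solve(np.eye(3), np.zeros(3)), np.zeros(3))

    def test_kkt_on_random_problems(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            A = rng.random((20, 15))
            b = rng.normal(size=20)
            x = nnls_solve(A, b)
            assert np.all(x >= 0)
            assert kkt_satisfied(A, b, x)

    def test_noiseless_sparse_recovery(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            A = rng.random((32, 40)) + 0.1
            x_true = np.zeros(40)
            idx = rng.choice(40, size=3, replace=False)
            x_true[idx] = rng.uniform(0.5, 2.0, size=3)
            x = nnls_solve(A, A @ x_true)
            assert np.abs(A @ x - A @ x_true).max() < 1e-8

    def test_matches_exhaustive_active_set_search(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            A = rng.random((10, 8))
            b = rng.normal(size=10)
            x = nnls_solve(A, b)
            _, obj_bf = brute_force_nnls(A, b)
            resid = A @ x - b
            assert float(resid @ resid) <= obj_bf + 1e-9


class TestRegularizedNnls:
    def test_zero_signal(self):
        A = np.random.default_rng(0).random((8, 5))
        x, mu, chi2, chi2_0, flags = regularized_nnls(A, np.zeros(8))
        assert np.all(x == 0) and chi2 == 0 and mu == 0 and flags == ()

    def test_chi2_monotone_in_mu(self):
        rng = np.random.default_rng(1)
        params = SequenceParams()
        basis = build_decay_basis(T2Grid.logspaced(), params).matrix
        sig = basis @ np.abs(rng.random(40)) + rng.normal(0, 0.01, 32)
        sig = np.abs(sig)
        from scipy.optimize import nnls as snnls

        chis = []
        for mu in np.logspace(-6, 1, 12):
            aug = np.vstack([basis, mu * np.eye(40)])
            x, _ = snnls(aug, np.concatenate([sig, np.zeros(40)]))
            r = basis @ x - sig
            chis.append(float(r @ r))
        assert np.all(np.diff(chis) >= -1e-12)

    def test_two_pool_window_mass(self, params, grid):
        basis = build_decay_basis(grid, params).matrix
        # construct signal from the basis itself at the grid points nearest 20/80 ms
        i20 = int(np.argmin(np.abs(grid.values - 20.0)))
        i80 = int(np.argmin(np.abs(grid.values - 80.0)))
        x_true = np.zeros(40)
        x_true[i20], x_true[i80] = 0.15, 0.85
        sig = basis @ x_true
        x, mu, chi2, chi2_0, flags = regularized_nnls(basis, sig)
        mw, *_ = compartmentalize(T2Spectrum(x, grid), CompartmentBoundaries())
        assert mw == pytest.approx(0.15, abs=0.02)

    def test_window_achieved_on_noisy_signal(self, params, grid):
        rng = np.random.default_rng(4)
        basis = build_decay_basis(grid, params).matrix
        sig = np.abs(
            three_pool_signal(180.0, [(0.1, 20), (0.85, 80), (0.05, 1000)], params)
            + rng.normal(0, 0.005, 32)
        )
        x, mu, chi2, chi2_0, flags = regularized_nnls(basis, sig)
        assert flags == ()
        assert 1.02 <= chi2 / chi2_0 <= 1.025
        assert mu > 0

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            regularized_nnls(np.eye(3), np.ones(3), chi2_window=(0.9, 1.2))


class TestEstimateFlipAngle:
    def test_generator_recovery_at_180(self, params, grid):
        sig = three_pool_signal(180.0, [(0.1, 20), (0.85, 80), (0.05, 1000)], params)
        alpha, flags = estimate_flip_angle(sig, grid, params)
        assert alpha == pytest.approx(180.0, abs=0.5)
        assert flags == ()

    def test_generator_recovery_at_155(self, params, grid):
        sig = three_pool_signal(155.0, [(0.2, 20), (0.8, 80)], params)
        alpha, _ = estimate_flip_angle(sig, grid, params)
        assert alpha == pytest.approx(155.0, abs=1.0)

    def test_noisy_recovery_monte_carlo(self, params, grid):
        rng = np.random.default_rng(6)
        sig0 = three_pool_signal(155.0, [(0.2, 20), (0.8, 80)], params)
        cache = {}
        recovered = []
        for _ in range(100):
            sig = np.abs(sig0 + rng.normal(0, sig0[0] / 100.0, 32))
            alpha, _ = estimate_flip_angle(sig, grid, params, basis_cache=cache)
            recovered.append(alpha)
        mean, spread = np.mean(recovered), np.std(recovered)
        assert mean == pytest.approx(155.0, abs=2.0), f"spread={spread:.2f}"

    def test_flat_objective_flagged(self, params, grid):
        alpha, flags = estimate_flip_angle(np.zeros(32), grid, params)
        assert alpha == pytest.approx(135.0)
        assert "flat_flip_objective" in flags

    def test_deterministic(self, params, grid):
        sig = three_pool_signal(160.0, [(0.3, 30), (0.7, 90)], params)
        assert estimate_flip_angle(sig, grid, params) == estimate_flip_angle(sig, grid, params)


class TestFitVoxel:
    def test_noiseless_three_pool_recovery(self, params, grid):
        sig = three_pool_signal(165.0, [(0.10, 20), (0.80, 80), (0.10, 1000)], params)
        res = fit_voxel(sig, params, grid)
        mw, iew, fw, _ = compartmentalize(res.spectrum, CompartmentBoundaries())
        assert mw == pytest.approx(0.10, abs=0.03)
        assert iew == pytest.approx(0.80, abs=0.03)
        assert fw == pytest.approx(0.10, abs=0.03)
        assert res.flip_deg == pytest.approx(165.0, abs=1.0)

    def test_background_voxel(self, params, grid):
        res = fit_voxel(np.zeros(32), params, grid)
        assert res.background
        assert res.snr == 0
        assert res.spectrum.total == 0
        assert "background" in res.flags

    def test_free_water_only(self, params, grid):
        sig = three_pool_signal(180.0, [(1.0, 1000)], params)
        res = fit_voxel(sig, params, grid)
        mass_above_250 = res.spectrum.amplitudes[grid.values > 250].sum()
        assert mass_above_250 / res.spectrum.total >= 0.95

    def test_kkt_certificate_held(self, params, grid):
        rng = np.random.default_rng(9)
        sig = np.abs(
            three_pool_signal(170.0, [(0.1, 20), (0.9, 80)], params) + rng.normal(0, 0.005, 32)
        )
        res = fit_voxel(sig, params, grid)
        # the regularized solution satisfies KKT for the augmented problem
        aug = np.vstack(
            [build_decay_basis(grid, params.with_flip(res.flip_deg)).matrix, res.mu * np.eye(40)]
        )
        aug_sig = np.concatenate([sig, np.zeros(40)])
        assert kkt_satisfied(aug, aug_sig, res.spectrum.amplitudes, rtol=1e-6)

    def test_negative_signal_rejected(self, params, grid):
        sig = -np.ones(32)
        with pytest.raises(ValueError):
            fit_voxel(sig, params, grid)

    def test_t1_insensitivity_at_180(self, grid):
        """Fractions move < 1% when the assumed T1 spans [600, 2000] ms."""
        fractions = []
        for t1 in (600.0, 1000.0, 2000.0):
            p = SequenceParams(t1_assumed=t1)
            sig = three_pool_signal(180.0, [(0.1, 20), (0.85, 80), (0.05, 1000)], p)
            res = fit_voxel(sig, p, grid)
            fractions.append(compartmentalize(res.spectrum, CompartmentBoundaries())[:3])
        fractions = np.array(fractions)
        assert np.abs(fractions - fractions[0]).max() < 0.01

    def test_basis_cache_identical_to_recompute(self, params, grid):
        rng = np.random.default_rng(10)
        sig = np.abs(
            three_pool_signal(160.0, [(0.15, 25), (0.85, 85)], params)
            + rng.normal(0, 0.004, 32)
        )
        cache = {}
        res_cached = fit_voxel(sig, params, grid, basis_cache=cache)
        res_fresh = fit_voxel(sig, params, grid)
        assert res_cached.flip_deg == res_fresh.flip_deg
        np.testing.assert_array_equal(
            res_cached.spectrum.amplitudes, res_fresh.spectrum.amplitudes
        )


class TestFitVolume:
    def test_small_phantom_volume(self, params, grid):
        sig = three_pool_signal(170.0, [(0.1, 20), (0.85, 80), (0.05, 1000)], params)
        vol = np.tile(sig, (4, 4, 1, 1))
        mask = np.ones((4, 4, 1), dtype=bool)
        res = fit_volume(vol, mask, params, grid)
        assert (~res.background).sum() == 16
        mw_mass = res.spectra[..., grid.values < 40].sum(axis=-1)
        total = res.spectra.sum(axis=-1)
        assert np.abs(mw_mass / total - 0.1).max() < 0.03

    def test_empty_mask(self, params, grid):
        vol = np.zeros((3, 3, 2, 32))
        res = fit_volume(vol, np.zeros((3, 3, 2), dtype=bool), params, grid)
        assert res.background.all()
        assert res.spectra.sum() == 0

    def test_identical_signals_identical_results(self, params, grid):
        sig = three_pool_signal(165.0, [(0.2, 30), (0.8, 90)], params)
        vol = np.tile(sig, (2, 3, 1, 1))
        mask = np.ones((2, 3, 1), dtype=bool)
        res = fit_volume(vol, mask, params, grid)
        ref = res.spectra[0, 0, 0]
        for i in range(2):
            for j in range(3):
                np.testing.assert_array_equal(res.spectra[i, j, 0], ref)

    def test_shape_mismatch(self, params, grid):
        with pytest.raises(ValueError):
            fit_volume(np.zeros((2, 2, 2, 32)), np.zeros((3, 3, 3), dtype=bool), params, grid)
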