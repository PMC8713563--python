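"""Intrinsic connectivity distribution: survival curves, model fitting,
subject maps."""

import numpy as np
import pytest
from scipy import stats

from icdpipe.icd import (
    TAU_GRID,
    ICDMaps,
    SurvivalCurve,
    fit_icd,
    grid_search_icd,
    icd_model,
    icd_subject,
    smooth_parameter_map,
    survival_from_correlations,
    voxel_correlations,
)
from icdpipe.images import Mask3D, make_affine

from conftest import box_mask, make_volume


def model_curve(alpha, beta):
    return SurvivalCurve(TAU_GRID, icd_model(TAU_GRID, alpha, beta), 1000)


def factor_volume(rng, rho, n_vox=60, n_t=200, shape=None):
    """Single-factor community series with exact signal correlation rho."""
    f = rng.standard_normal(n_t)
    e = rng.standard_normal((n_vox, n_t))
    ts = np.sqrt(rho) * f + np.sqrt(1 - rho) * e
    if shape is None:
        side = int(np.ceil(n_vox ** (1 / 3)))
        shape = (side, side, side)
    data = np.zeros(shape + (n_t,))
    data.reshape(-1, n_t)[:n_vox] = ts
    mask = np.zeros(shape, bool)
    mask.reshape(-1)[:n_vox] = True
    return make_volume(data), Mask3D(mask, make_affine(3.0))


class TestSurvival:
    def test_hand_computed_two_correlations(self):
        """r = {0.5, -0.2}: one positive value, so survival is a step at 0.5."""
        curve = survival_from_correlations(np.array([0.5, -0.2]))
        assert curve.n_positive == 1
        np.testing.assert_array_equal(curve.survival[curve.tau < 0.5], 1.0)
        np.testing.assert_array_equal(curve.survival[curve.tau >= 0.5], 0.0)

    def test_perfect_correlation_survival_one(self):
        curve = survival_from_correlations(np.full(50, 0.999))
        np.testing.assert_array_equal(curve.survival, 1.0)

    def test_all_negative_returns_none(self):
        assert survival_from_correlations(np.array([-0.1, -0.5])) is None

    def test_null_voxel_matches_half_normal_tail(self, rng):
        """Independent voxel: positive correlations follow the half-normal
        null, so survival(tau) ~ 2*(1 - Phi(tau*sqrt(T)))."""
        n_t = 2000
        r = np.tanh(rng.standard_normal(3000) / np.sqrt(n_t - 3))
        curve = survival_from_correlations(r)
        for tau_val in (0.02, 0.04):
            expected = 2 * stats.norm.sf(tau_val * np.sqrt(n_t - 3))
            got = curve.survival[np.searchsorted(curve.tau, tau_val)]
            assert got == pytest.approx(expected, abs=0.05)
        assert curve.survival[curve.tau >= 3 / np.sqrt(n_t)].max() < 0.05

    def test_monotone_validation(self):
        with pytest.raises(ValueError):
            SurvivalCurve(TAU_GRID, np.linspace(0, 1, 99), 10)

    def test_voxel_correlations_wiring(self, rng):
        vol, mask = factor_volume(rng, 0.5, n_vox=10, n_t=500)
        vox = tuple(np.argwhere(mask.data)[0])
        curve = voxel_correlations(vol, mask, vox)
        ts = vol.data[mask.data]
        r = np.corrcoef(ts)[0, 1:]
        expected = survival_from_correlations(r)
        np.testing.assert_allclose(curve.survival, expected.survival, atol=1e-12)


class TestFit:
    def test_exact_recovery(self):
        fit = fit_icd(model_curve(2.0, 1.5))
        assert fit.success
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.beta == pytest.approx(1.5, abs=1e-6)
        assert fit.rss < 1e-12

    def test_grid_oracle_confirms_global_optimum(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.5, 4), rng.uniform(0.5, 3)
            curve = model_curve(a, b)
            fit = fit_icd(curve)
            ga, gb, grss = grid_search_icd(
                curve, np.linspace(0.2, 6, 80), np.linspace(0.2, 4, 60)
            )
            assert fit.rss <= grss + 1e-12

    def test_dominated_curve_gets_larger_alpha(self, rng):
        """Uniformly lower survival (fewer strong connections) => larger alpha."""
        for _ in range(20):
            a = rng.uniform(0.5, 2.0)
            b = rng.uniform(0.8, 2.5)
            dominating = model_curve(a, b)
            dominated = model_curve(a * rng.uniform(1.2, 2.0), b)
            assert np.all(dominating.survival >= dominated.survival)
            f1, f2 = fit_icd(dominating), fit_icd(dominated)
            assert f2.alpha > f1.alpha

    def test_flat_survival_fails(self):
        curve = SurvivalCurve(TAU_GRID, np.ones_like(TAU_GRID), 100)
        fit = fit_icd(curve)
        assert not fit.success
        assert np.isnan(fit.alpha)

    def test_noisy_curve_recovery(self, rng):
        surv = icd_model(TAU_GRID, 1.5, 1.2)
        noisy = np.clip(surv + rng.normal(0, 0.005, surv.shape), 0, 1)
        noisy = np.minimum.accumulate(noisy)
        fit = fit_icd(SurvivalCurve(TAU_GRID, noisy, 500))
        assert fit.success
        assert fit.alpha == pytest.approx(1.5, rel=0.1)


class TestSubjectMaps:
    def test_high_coupling_community_has_lower_alpha(self, rng):
        """Smaller alpha = higher connectivity: the coupled block must sit
        below independent background voxels."""
        n_t = 300
        f = rng.standard_normal(n_t)
        coupled = np.sqrt(0.5) * f + np.sqrt(0.5) * rng.standard_normal((30, n_t))
        background = rng.standard_normal((30, n_t))
        data = np.vstack([coupled, background]).reshape(4, 3, 5, n_t)
        vol = make_volume(data)
        mask = box_mask((4, 3, 5))
        maps = icd_subject(vol, mask)
        alpha = maps.alpha[mask.data]
        assert np.nanmean(alpha[:30]) < np.nanmean(alpha[30:])

    def test_alpha_decreases_with_coupling(self):
        """Raising within-community coupling 0.3 -> 0.6 lowers mean alpha
        (averaged over 10 seeds)."""
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            state = rng.bit_generator.state
            vol_lo, mask = factor_volume(rng, 0.3, n_vox=40, n_t=124)
            rng2 = np.random.default_rng(seed)
            vol_hi, _ = factor_volume(rng2, 0.6, n_vox=40, n_t=124)
            a_lo = np.nanmean(icd_subject(vol_lo, mask).alpha)
            a_hi = np.nanmean(icd_subject(vol_hi, mask).alpha)
            diffs.append(a_hi - a_lo)
        assert np.mean(diffs) < 0
        assert np.mean(np.array(diffs) < 0) >= 0.9

    def test_invariant_to_linear_rescaling(self, rng):
        vol, mask = factor_volume(rng, 0.4, n_vox=20, n_t=150)
        maps_a = icd_subject(vol, mask)
        scaled = vol.data * rng.uniform(0.5, 5.0, vol.shape3d)[..., None] + \
            rng.normal(0, 10, vol.shape3d)[..., None]
        maps_b = icd_subject(make_volume(scaled), mask)
        np.testing.assert_allclose(maps_a.alpha, maps_b.alpha, rtol=1e-6, equal_nan=True)

    def test_chunking_invariance(self, rng):
        vol, mask = factor_volume(rng, 0.4, n_vox=25, n_t=150)
        a = icd_subject(vol, mask, chunk_size=7)
        b = icd_subject(vol, mask, chunk_size=256)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_voxel_permutation_equivariance(self, rng):
        vol, mask = factor_volume(rng, 0.4, n_vox=24, n_t=150, shape=(24, 1, 1))
        perm = rng.permutation(24)
        vol_p = make_volume(vol.data[perm])
        a = icd_subject(vol, mask)
        b = icd_subject(vol_p, mask)
        np.testing.assert_allclose(a.alpha.ravel()[perm], b.alpha.ravel(), rtol=1e-9)

    def test_zero_variance_voxel_marked_failed(self, rng):
        vol, mask = factor_volume(rng, 0.4, n_vox=20, n_t=150)
        vol.data[tuple(np.argwhere(mask.data)[0])] = 1.0  # constant series
        maps = icd_subject(vol, mask)
        v0 = tuple(np.argwhere(mask.data)[0])
        assert not maps.valid[v0]
        assert np.isnan(maps.alpha[v0])

    def test_agrees_with_thresholded_degree(self, rng):
        """ICD generalizes thresholded degree: rank correlation between
        (-alpha) and degree at tau=0.25 must be high on block data."""
        n_t = 300
        rhos = np.repeat([0.1, 0.3, 0.5, 0.7], 15)
        f = rng.standard_normal(n_t)
        ts = np.array([
            np.sqrt(r) * f + np.sqrt(1 - r) * rng.standard_normal(n_t) for r in rhos
        ])
        data = ts.reshape(6, 5, 2, n_t)
        vol, mask = make_volume(data), box_mask((6, 5, 2))
        maps = icd_subject(vol, mask)
        z = ts - ts.mean(1, keepdims=True)
        z /= z.std(1, keepdims=True)
        corr = z @ z.T / n_t
        np.fill_diagonal(corr, 0)
        degree = (corr > 0.25).sum(1)
        rho_rank = stats.spearmanr(-maps.alpha[mask.data], degree).statistic
        assert rho_rank > 0.8


class TestParameterSmoothing:
    def _maps(self, alpha, mask):
        return ICDMaps(
            alpha=alpha, beta=np.ones_like(alpha), rss=np.zeros_like(alpha),
            n_positive=np.ones(alpha.shape, int), valid=np.isfinite(alpha),
            affine=make_affine(3.0),
        )

    def test_constant_map_unchanged(self):
        mask = box_mask((6, 6, 6))
        maps = self._maps(np.full((6, 6, 6), 2.5), mask)
        out = smooth_parameter_map(maps, 4.0, mask)
        np.testing.assert_allclose(out.alpha, 2.5, rtol=1e-10)

    def test_failed_voxels_stay_nan_and_do_not_contaminate(self):
        mask = box_mask((6, 6, 6))
        alpha = np.full((6, 6, 6), 2.0)
        alpha[3, 3, 3] = np.nan  # failed fit
        out = smooth_parameter_map(self._maps(alpha, mask), 4.0, mask)
        assert np.isnan(out.alpha[3, 3, 3])
        valid = np.isfinite(alpha)
        np.testing.assert_allclose(out.alpha[valid], 2.0, rtol=1e-10)
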