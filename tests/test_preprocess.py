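"""Preprocessing: truncation, censoring, smoothing, nuisance GLM and
tissue regression."""

import numpy as np
import pytest

from icdpipe.images import Mask3D, make_affine
from icdpipe.preprocess import (
    MotionTrace,
    PreprocessError,
    censor_frames,
    erode_mask,
    nuisance_glm,
    preprocess_subject,
    smooth_gaussian,
    smooth_volume,
    tissue_regression,
    truncate_initial,
)
from icdpipe.simulate import SOMATOMOTOR, SimDesign, simulate_cohort

from conftest import box_mask, make_volume, zero_motion


def flat_volume(shape3d, n_t, rng=None, tr=3.0):
    rng = rng or np.random.default_rng(0)
    return make_volume(rng.standard_normal(shape3d + (n_t,)), tr=tr)


class TestTruncateCensor:
    def test_truncation_removes_first_four(self):
        vol = flat_volume((4, 4, 3), 124)
        out, mot = truncate_initial(vol, zero_motion(124), 4)
        assert out.n_frames == 120
        assert mot.n_frames == 120
        np.testing.assert_array_equal(out.data, vol.data[..., 4:])

    def test_motion_length_mismatch_rejected(self):
        with pytest.raises(PreprocessError):
            truncate_initial(flat_volume((2, 2, 2), 20), zero_motion(19))

    def test_boundary_jump_not_censored_strict(self):
        """A 0.3 mm jump is retained; only >0.3 mm trips the rule."""
        n = 10
        params = np.zeros((n, 6))
        params[1:, 0] = 0.3          # frame 0->1 jumps exactly 0.3
        params[2:, 0] = 0.3 + 0.4    # frame 1->2 jumps 0.4
        vol = flat_volume((3, 3, 3), n)
        out = censor_frames(vol, MotionTrace(params))
        assert 1 not in out.censored_frames
        assert 2 in out.censored_frames

    def test_no_false_censoring_on_gaussian_data(self):
        """Calibrated outlier rule: clean Gaussian data censors nothing."""
        vol = flat_volume((6, 6, 4), 120, np.random.default_rng(42))
        out = censor_frames(vol, zero_motion(120))
        assert len(out.censored_frames) == 0

    def test_spike_frame_censored_by_outlier_rule(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 6, 4, 60))
        data[..., 30] += 10.0  # global artifact on one frame
        out = censor_frames(make_volume(data), zero_motion(60))
        assert 30 in out.censored_frames

    def test_all_frames_censored_degenerate(self):
        n = 12
        params = np.zeros((n, 6))
        params[::2, 0] = 5.0  # every transition jumps
        vol = flat_volume((2, 2, 2), n)
        out = censor_frames(vol, MotionTrace(params))
        assert out.censor_fraction == pytest.approx(
            len(out.censored_frames) / n
        )
        assert out.censor_fraction > 0.9

    def test_framewise_displacement_length_and_sign(self):
        mt = MotionTrace(np.cumsum(np.ones((5, 6)), axis=0))
        fd = mt.framewise_displacement()
        assert fd.shape == (4,)
        assert np.all(fd >= 0)


class TestSmoothing:
    def test_constant_image_unchanged_in_mask(self):
        mask = box_mask((8, 8, 8))
        img = np.full((8, 8, 8), 3.7)
        out = smooth_gaussian(img, make_affine(3.0), 6.0, mask)
        np.testing.assert_allclose(out, 3.7, rtol=1e-10)

    def test_no_bleed_from_outside_mask(self):
        """Signal outside the mask never leaks in (kernel renormalized)."""
        mask_arr = np.zeros((10, 10, 10), dtype=bool)
        mask_arr[2:8, 2:8, 2:8] = True
        mask = Mask3D(mask_arr, make_affine(3.0))
        img = np.where(mask_arr, 1.0, 1000.0)
        out = smooth_gaussian(img, make_affine(3.0), 6.0, mask)
        np.testing.assert_allclose(out[mask_arr], 1.0, rtol=1e-10)

    def test_delta_mass_approximately_preserved(self):
        mask = box_mask((12, 12, 12))
        img = np.zeros((12, 12, 12))
        img[6, 6, 6] = 1.0
        out = smooth_gaussian(img, make_affine(3.0), 6.0, mask)
        assert out.sum() == pytest.approx(1.0, abs=0.05)

    def test_matches_direct_space_convolution(self):
        """Separable direct-space convolution oracle on an 8x8x8 grid."""
        rng = np.random.default_rng(5)
        img = rng.standard_normal((8, 8, 8))
        fwhm, vox = 4.0, 3.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        radius = int(4.0 * sigma + 0.5)  # matches scipy's default truncation
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        expected = img.copy()
        for axis in range(3):
            padded = np.zeros(np.array(expected.shape) + 2 * radius * (np.arange(3) == axis))
            sl = [slice(None)] * 3
            sl[axis] = slice(radius, radius + 8)
            padded[tuple(sl)] = expected
            conv = np.zeros_like(expected)
            for j, w in enumerate(k):
                sl2 = [slice(None)] * 3
                sl2[axis] = slice(j, j + 8)
                conv += w * padded[tuple(sl2)]
            expected = conv
        out = smooth_gaussian(img, make_affine(vox), fwhm, mask=None)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_tiny_fwhm_warns(self):
        with pytest.warns(UserWarning, match="near-identity"):
            smooth_gaussian(np.zeros((4, 4, 4)), make_affine(3.0), 1.0)


class TestNuisanceGLM:
    def _vol_with_series(self, series, shape=(3, 3, 2)):
        data = np.broadcast_to(series, shape + (len(series),)).copy()
        return make_volume(data)

    def test_in_band_sinusoid_retained(self):
        t = np.arange(120) * 3.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = nuisance_glm(self._vol_with_series(sig), zero_motion(120))
        ratio = out.data[0, 0, 0].std() / sig.std()
        assert ratio >= 0.95

    def test_slow_drift_removed(self):
        t = np.arange(120) * 3.0
        drift = np.sin(2 * np.pi * 0.005 * t)
        out = nuisance_glm(self._vol_with_series(drift), zero_motion(120))
        assert out.data[0, 0, 0].std() <= 0.05 * drift.std()

    def test_motion_regressor_annihilated(self):
        rng = np.random.default_rng(8)
        params = np.cumsum(rng.normal(0, 0.01, (120, 6)), axis=0)
        vol = self._vol_with_series(params[:, 2].copy())
        out = nuisance_glm(vol, MotionTrace(params))
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_zero_mean(self):
        vol = flat_volume((4, 4, 2), 120)
        out = nuisance_glm(vol, zero_motion(120))
        means = out.data[..., out.retained_frames].mean(axis=-1)
        np.testing.assert_allclose(means, 0.0, atol=1e-10)

    def test_censored_frames_excluded_and_zeroed(self):
        vol = flat_volume((2, 2, 2), 120)
        vol = censor_frames(vol, zero_motion(120))
        from dataclasses import replace

        vol = replace(vol, censored_frames=frozenset({5, 17}))
        out = nuisance_glm(vol, zero_motion(120))
        assert np.all(out.data[..., [5, 17]] == 0)

    def test_rank_deficiency_flagged(self):
        vol = flat_volume((2, 2, 2), 120)
        from dataclasses import replace

        vol = replace(vol, censored_frames=frozenset(range(100)))
        with pytest.raises(PreprocessError, match="rank-deficient"):
            nuisance_glm(vol, zero_motion(120))


class TestTissueRegression:
    def _setup(self, rng, n_t=100):
        shape = (10, 6, 6)
        gm = np.zeros(shape, bool)
        gm[0:4] = True
        wm = np.zeros(shape, bool)
        wm[4:7] = True
        vent = np.zeros(shape, bool)
        vent[7:10] = True
        aff = make_affine(3.0)
        return shape, Mask3D(gm, aff), Mask3D(wm, aff), Mask3D(vent, aff)

    def test_wm_mean_signal_removed(self, rng):
        shape, gm, wm, vent = self._setup(rng)
        wm_sig = rng.standard_normal(100)
        data = np.zeros(shape + (100,))
        data[wm.data] = wm_sig + 0.05 * rng.standard_normal((wm.n_voxels, 100))
        data[vent.data] = rng.standard_normal((vent.n_voxels, 100))
        data[gm.data] = wm_sig  # gray matter is exactly the WM mean signal
        out = tissue_regression(make_volume(data), wm, vent, gm_mask=gm)
        assert np.abs(out.data[gm.data]).max() < 0.05

    def test_three_ventricle_components_removed(self, rng):
        """Known mixing of 3 ventricle sources into GM leaves <=1% variance."""
        shape, gm, wm, vent = self._setup(rng)
        sources = rng.standard_normal((3, 100))
        data = np.zeros(shape + (100,))
        data[wm.data] = rng.standard_normal((wm.n_voxels, 100)) * 0.1
        loadings = rng.normal(0, 1, (vent.n_voxels, 3))
        data[vent.data] = loadings @ sources
        gm_mix = rng.normal(0, 1, (gm.n_voxels, 3))
        data[gm.data] = gm_mix @ sources
        out = tissue_regression(make_volume(data), wm, vent, gm_mask=gm)
        var_in = (gm_mix @ sources).var(axis=1).mean()
        var_out = out.data[gm.data].var(axis=1).mean()
        assert var_out <= 0.01 * var_in

    def test_orthogonal_signal_untouched(self, rng):
        """A GM signal orthogonal to all nuisance regressors survives."""
        shape, gm, wm, vent = self._setup(rng)
        data = np.zeros(shape + (100,))
        data[wm.data] = rng.standard_normal((wm.n_voxels, 100))
        data[vent.data] = rng.standard_normal((vent.n_voxels, 100))
        vol = make_volume(data)
        from icdpipe.preprocess import tissue_regressors

        reg = tissue_regressors(vol, wm, vent)
        basis = np.column_stack([np.ones(100), reg])
        q, _ = np.linalg.qr(np.column_stack([basis, rng.standard_normal(100)]))
        ortho = q[:, -1]  # orthogonal to intercept + all regressors
        data[gm.data] = ortho
        out = tissue_regression(make_volume(data), wm, vent, gm_mask=gm)
        c = np.corrcoef(out.data[gm.data][0], ortho)[0, 1]
        assert c >= 0.99

    def test_erosion_six_connected(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[1:4, 1:4, 1:4] = True
        eroded = erode_mask(Mask3D(arr, make_affine(3.0)))
        assert eroded.n_voxels == 1
        assert eroded.data[2, 2, 2]

    def test_empty_erosion_falls_back(self):
        arr = np.zeros((4, 4, 4), bool)
        arr[1, 1, 1] = True
        with pytest.warns(UserWarning, match="eroded mask is empty"):
            eroded = erode_mask(Mask3D(arr, make_affine(3.0)))
        assert eroded.n_voxels == 1


class TestFullChain:
    def test_nuisance_regression_improves_coupling_estimates(self):
        """With planted drift and WM/ventricle mixing, within-community
        correlations after the nuisance stages sit closer to the generating
        coupling than before them (paired over 20 subjects; smoothing is
        kept out of both arms since it deliberately pools neighbors)."""
        design = SimDesign(
            n_subjects=20, seed=17, high_motion_frac=0.0,
            drift_amp=1.5, nuisance_mix=0.6, noise_sd=0.2,  # pronounced nuisance
        )
        cohort = simulate_cohort(design)
        geo = cohort.geometry
        sm = geo.community_map == SOMATOMOTOR
        before_errs, after_errs = [], []
        for vol, mot, truth in zip(
            cohort.images, cohort.motion, cohort.truth.per_subject
        ):
            rho = truth.coupling_somatomotor

            def mean_corr(ts):
                r = np.corrcoef(ts)
                return r[np.triu_indices_from(r, k=1)].mean()

            trunc, trace = truncate_initial(vol, MotionTrace(mot))
            trunc = censor_frames(trunc, trace)
            try:
                clean = nuisance_glm(trunc, trace)
            except PreprocessError:
                continue  # heavily censored subject flagged, as in the pipeline
            clean = tissue_regression(clean, geo.wm, geo.ventricles)
            before_errs.append(abs(mean_corr(trunc.retained_data()[sm]) - rho))
            after_errs.append(abs(mean_corr(clean.retained_data()[sm]) - rho))
        assert len(after_errs) >= 12
        # paired comparison: cleaning must cut the mean error substantially
        assert np.mean(after_errs) < 0.6 * np.mean(before_errs)

    def test_deterministic(self):
        design = SimDesign(n_subjects=2, seed=23)
        cohort = simulate_cohort(design)
        geo = cohort.geometry
        args = (cohort.images[0], MotionTrace(cohort.motion[0]), geo.gm, geo.wm, geo.ventricles)
        a, _ = preprocess_subject(*args)
        b, _ = preprocess_subject(*args)
        assert np.array_equal(a.data, b.data)
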