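"""Core resting-state preprocessing on registered volumes.

Stage order (fixed, logged): truncate initial frames -> censor
high-motion/outlier frames -> spatial smoothing -> motion + band-limit
nuisance GLM -> tissue-based regression.

Band limiting is done inside the GLM by regressing out sine/cosine
pairs for every discrete frequency outside the retained band; this
treats "frequency components" as ordinary nuisance regressors and stays
exact when frames have been censored (the regressors are evaluated only
at retained frame times).

Frame censoring follows two rules: the Euclidean norm of the
frame-to-frame translation difference strictly exceeds 0.3 mm, or the
frame's fraction of outlier voxels (|value - voxel median| beyond 3
robust SDs) strictly exceeds 10%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .images import Mask3D, Volume4D, voxel_sizes

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
MAD_TO_SIGMA = 1.4826

#: residual temporal degrees of freedom below which a subject's nuisance
#: fit (and any correlation computed on its residuals) is unusable
MIN_RESIDUAL_DF = 15


class PreprocessError(RuntimeError):
    """Raised when a subject cannot be preprocessed (flagged, not silently fit)."""


@dataclass
class MotionTrace:
    """Six rigid-body parameters per frame: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray  # (n_frames, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion params must be (n_frames, 6), got {self.params.shape}")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def derivatives(self) -> np.ndarray:
        """First differences, zero-padded at the first frame."""
        d = np.diff(self.params, axis=0)
        return np.vstack([np.zeros((1, 6)), d])

    def framewise_displacement(self, rotation_radius_mm: float | None = None) -> np.ndarray:
        """Per-transition displacement, length ``n_frames - 1``.

        By default the Euclidean norm of the translation difference; if
        ``rotation_radius_mm`` is given, rotation differences are
        converted to arc length at that radius and added in quadrature.
        """
        dt = np.diff(self.params[:, :3], axis=0)
        fd = np.linalg.norm(dt, axis=1)
        if rotation_radius_mm is not None:
            dr = np.diff(self.params[:, 3:], axis=0) * rotation_radius_mm
            fd = np.sqrt(fd**2 + np.sum(dr**2, axis=1))
        return fd

    def mean_fd(self, rotation_radius_mm: float | None = None) -> float:
        fd = self.framewise_displacement(rotation_radius_mm)
        return float(fd.mean()) if len(fd) else 0.0


def truncate_initial(vol: Volume4D, motion: MotionTrace, n_discard: int = 4
                     ) -> tuple[Volume4D, MotionTrace]:
    """Drop the first ``n_discard`` frames from both image and motion trace."""
    if motion.n_frames != vol.n_frames:
        raise PreprocessError(
            f"motion has {motion.n_frames} frames but image has {vol.n_frames}"
        )
    if vol.n_frames <= n_discard:
        raise PreprocessError("too few frames to truncate")
    out = Volume4D(vol.data[..., n_discard:], vol.affine, vol.tr_seconds)
    return out, MotionTrace(motion.params[n_discard:])


def outlier_fractions(vol: Volume4D, brain_mask: Mask3D | None = None,
                      n_sigma: float = 3.0) -> np.ndarray:
    """Fraction of outlier voxels per frame.

    A voxel-frame is an outlier when it deviates from the voxel's
    temporal median by more than ``n_sigma`` robust (MAD-based) SDs.
    """
    if brain_mask is not None:
        ts = vol.data[brain_mask.data, :]
    else:
        ts = vol.data.reshape(-1, vol.n_frames)
    med = np.median(ts, axis=1, keepdims=True)
    mad = np.median(np.abs(ts - med), axis=1, keepdims=True)
    sigma = MAD_TO_SIGMA * mad
    ok = sigma[:, 0] > 0
    if not ok.any():
        return np.zeros(vol.n_frames)
    dev = np.abs(ts[ok] - med[ok]) > n_sigma * sigma[ok]
    return dev.mean(axis=0)


def censor_frames(vol: Volume4D, motion: MotionTrace, movement_mm: float = 0.3,
                  outlier_frac: float = 0.10, brain_mask: Mask3D | None = None) -> Volume4D:
    """Mark frames as censored; returns a new volume with ``censored_frames`` set.

    Frame ``k+1`` is censored when the translation jump from frame ``k``
    strictly exceeds ``movement_mm``; any frame whose outlier-voxel
    fraction strictly exceeds ``outlier_frac`` is censored as well.
    """
    if motion.n_frames != vol.n_frames:
        raise PreprocessError(
            f"motion has {motion.n_frames} frames but image has {vol.n_frames}"
        )
    fd = motion.framewise_displacement()
    censored = set((np.flatnonzero(fd > movement_mm) + 1).tolist())
    censored |= set(np.flatnonzero(outlier_fractions(vol, brain_mask) > outlier_frac).tolist())
    return replace(vol, censored_frames=frozenset(censored))


def smooth_gaussian(data: np.ndarray, affine: np.ndarray, fwhm_mm: float,
                    mask: Mask3D | None = None) -> np.ndarray:
    """Mask-renormalized Gaussian smoothing of a 3D map or 4D series.

    The kernel is renormalized over in-mask voxels (normalized
    convolution), so no signal bleeds across the mask boundary and a
    constant in-mask image is returned unchanged.  Output is zero
    outside the mask.
    """
    data = np.asarray(data, dtype=np.float64)
    vs = voxel_sizes(affine)
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if fwhm_mm < 0.5 * vs.min():
        warnings.warn(
            f"FWHM {fwhm_mm} mm is below half a voxel ({vs.min()} mm); "
            "smoothing is near-identity", stacklevel=2,
        )
    sigma_vox = FWHM_TO_SIGMA * fwhm_mm / vs
    sig = tuple(sigma_vox) + ((0.0,) if data.ndim == 4 else ())

    if mask is None:
        return ndimage.gaussian_filter(data, sigma=sig, mode="constant")
    m = mask.data.astype(np.float64)
    den = ndimage.gaussian_filter(m, sigma=tuple(sigma_vox), mode="constant")
    masked = data * (m[..., None] if data.ndim == 4 else m)
    num = ndimage.gaussian_filter(masked, sigma=sig, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / (den[..., None] if data.ndim == 4 else den)
    keep = mask.data if data.ndim == 3 else mask.data[..., None] & np.ones_like(out, bool)
    out = np.where(keep, out, 0.0)
    return out


def smooth_volume(vol: Volume4D, fwhm_mm: float, mask: Mask3D | None = None) -> Volume4D:
    return replace(vol, data=smooth_gaussian(vol.data, vol.affine, fwhm_mm, mask))


def _band_regressors(frame_idx: np.ndarray, n_frames: int, tr: float,
                     band: tuple[float, float]) -> np.ndarray:
    """Sine/cosine columns for frequencies outside ``band``, evaluated at
    the retained frame times (constant term excluded).

    Below the band the frequency grid runs in half-bin steps: slow
    drifts rarely sit on an exact DFT bin and would otherwise leak into
    the retained band.  Above the band the integer bins suffice, and
    the low-side grid stays small so the design does not eat into the
    residual degrees of freedom that the downstream correlation
    estimates depend on.
    """
    t = frame_idx * tr
    total_t = n_frames * tr
    cols = []
    j = 1.0
    while j / total_t < band[0] - 1e-12:
        w = 2.0 * np.pi * (j / total_t) * t
        cols.append(np.cos(w))
        cols.append(np.sin(w))
        j += 0.5
    for j in range(1, n_frames // 2 + 1):
        f = j / total_t
        if f <= band[1]:
            continue
        w = 2.0 * np.pi * f * t
        cols.append(np.cos(w))
        if j < (n_frames + 1) // 2:  # Nyquist bin has no sine component
            cols.append(np.sin(w))
    return np.column_stack(cols) if cols else np.empty((len(t), 0))


def _ols_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def nuisance_glm(vol: Volume4D, motion: MotionTrace,
                 band_hz: tuple[float, float] = (0.01, 0.08)) -> Volume4D:
    """Regress motion, motion derivatives and out-of-band Fourier
    components from every voxel (OLS over retained frames).

    Removing all Fourier components outside ``band_hz`` is a band-pass
    implemented inside the GLM; residuals retain only in-band signal.
    Censored frames are excluded from the fit and zeroed in the output.
    """
    if motion.n_frames != vol.n_frames:
        raise PreprocessError("motion/frame length mismatch")
    keep = vol.retained_frames
    X = np.column_stack([
        np.ones(len(keep)),
        motion.params[keep],
        motion.derivatives[keep],
        _band_regressors(keep, vol.n_frames, vol.tr_seconds, band_hz),
    ])
    # constant motion channels (e.g. an axis that never moves) carry no
    # information; drop them rather than fail the rank check
    variable = np.concatenate([[True], X[:, 1:].std(axis=0) > 0])
    X = X[:, variable]
    df_resid = len(keep) - np.linalg.matrix_rank(X)
    if df_resid < MIN_RESIDUAL_DF:
        raise PreprocessError(
            f"nuisance design rank-deficient: {len(keep)} retained frames, "
            f"{X.shape[1]} regressors leave {df_resid} residual df "
            f"(need >= {MIN_RESIDUAL_DF})"
        )
    Y = vol.data[..., keep].reshape(-1, len(keep)).T
    resid = _ols_residuals(Y, X)
    out = np.zeros_like(vol.data)
    out[..., keep] = resid.T.reshape(vol.shape3d + (len(keep),))
    return replace(vol, data=out)


def erode_mask(mask: Mask3D, iterations: int = 1) -> Mask3D:
    """Single-pass 6-connected erosion; falls back to the uneroded mask
    (with a warning) if erosion empties it."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask.data, structure=structure, iterations=iterations)
    if not eroded.any():
        warnings.warn("eroded mask is empty; using uneroded mask", stacklevel=2)
        return mask
    return Mask3D(eroded, mask.affine)


def tissue_regressors(vol: Volume4D, wm_mask: Mask3D, vent_mask: Mask3D,
                      n_pcs: int = 3) -> np.ndarray:
    """White-matter mean and ventricle principal-component time courses.

    Masks are eroded one voxel (6-neighborhood) first.  Ventricle
    regressors are the first ``n_pcs`` left singular vectors of the
    centered time x voxel matrix, scaled to unit variance; if the mask
    holds fewer voxels, the available count is used.
    """
    keep = vol.retained_frames
    wm = erode_mask(wm_mask)
    vent = erode_mask(vent_mask)
    wm_mean = vol.data[wm.data][:, keep].mean(axis=0)

    vts = vol.data[vent.data][:, keep].T  # (t_kept, n_vent)
    n_use = min(n_pcs, vts.shape[1])
    if n_use < n_pcs:
        logger.info("ventricle mask has %d voxels; using %d PCs", vts.shape[1], n_use)
    vts = vts - vts.mean(axis=0)
    u, s, _ = np.linalg.svd(vts, full_matrices=False)
    pcs = u[:, :n_use]
    sd = pcs.std(axis=0)
    sd[sd == 0] = 1.0
    pcs = pcs / sd
    return np.column_stack([wm_mean, pcs])


def tissue_regression(vol: Volume4D, wm_mask: Mask3D, vent_mask: Mask3D,
                      gm_mask: Mask3D | None = None, n_pcs: int = 3) -> Volume4D:
    """Regress WM mean + ventricle PCs (plus intercept) out of gray matter."""
    keep = vol.retained_frames
    reg = tissue_regressors(vol, wm_mask, vent_mask, n_pcs)
    X = np.column_stack([np.ones(len(keep)), reg])
    out = vol.data.copy()
    if gm_mask is None:
        Y = vol.data[..., keep].reshape(-1, len(keep)).T
        out[..., keep] = _ols_residuals(Y, X).T.reshape(vol.shape3d + (len(keep),))
    else:
        Y = vol.data[gm_mask.data][:, keep].T
        sub = out[gm_mask.data]
        sub[:, keep] = _ols_residuals(Y, X).T
        out[gm_mask.data] = sub
    return replace(vol, data=out)


@dataclass
class PreprocessSummary:
    mean_motion_per_tr: float
    censor_fraction: float
    n_censored: int
    n_frames: int


def preprocess_subject(
    vol: Volume4D,
    motion: MotionTrace,
    gm_mask: Mask3D,
    wm_mask: Mask3D,
    vent_mask: Mask3D,
    n_discard: int = 4,
    movement_mm: float = 0.3,
    outlier_frac: float = 0.10,
    fwhm_mm: float = 6.0,
    band_hz: tuple[float, float] = (0.01, 0.08),
    brain_mask: Mask3D | None = None,
) -> tuple[Volume4D, PreprocessSummary]:
    """Full preprocessing chain for one subject.

    Returns the residual volume and the motion summary consumed by QC.
    If too many frames are censored for the nuisance design to be
    estimable, a ``PreprocessError`` is raised by the GLM stage; the
    caller should record the subject as flagged (QC excludes such
    subjects via the censor fraction anyway).
    """
    vol, motion = truncate_initial(vol, motion, n_discard)
    vol = censor_frames(vol, motion, movement_mm, outlier_frac, brain_mask)
    summary = PreprocessSummary(
        mean_motion_per_tr=motion.mean_fd(),
        censor_fraction=vol.censor_fraction,
        n_censored=len(vol.censored_frames),
        n_frames=vol.n_frames,
    )
    vol = smooth_volume(vol, fwhm_mm, brain_mask)
    vol = nuisance_glm(vol, motion, band_hz)
    vol = tissue_regression(vol, wm_mask, vent_mask, gm_mask=None)
    return vol, summary
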