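"""Intrinsic connectivity distribution (ICD): a threshold-free voxel
connectivity summary.

For each gray-matter voxel the Pearson correlations to all other
gray-matter voxels are computed, negatives are discarded, and the
empirical survival function of the positive correlations (fraction
exceeding each threshold tau on a fixed grid) is fit with the
stretched-exponential decay model

    S(tau) = exp(-(alpha * tau)^beta),    alpha > 0, beta > 0.

alpha is an inverse scale: a voxel with many strong connections has a
slowly decaying survival curve and therefore a SMALL alpha, so lower
alpha means higher connectivity.  beta controls the decay shape.  Note
alpha comparisons across voxels are most interpretable between curves
of similar shape (similar beta); the model form is pluggable via
``icd_model``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .images import Mask3D, Volume4D
from .preprocess import smooth_gaussian

TAU_GRID = np.round(np.arange(1, 100) * 0.01, 2)  # 0.01 .. 0.99

#: restart lattice used when the default initialization fails to converge
ALPHA_RESTARTS = (0.5, 1.0, 2.0, 4.0)
BETA_RESTARTS = (0.5, 1.0, 2.0)

MIN_INTERIOR_POINTS = 5


def icd_model(tau: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Stretched-exponential survival model S(tau) = exp(-(alpha tau)^beta)."""
    with np.errstate(over="ignore"):
        expo = np.minimum((alpha * tau) ** beta, 745.0)  # cap before exp underflows
    return np.exp(-expo)


@dataclass
class SurvivalCurve:
    """Empirical survival of a voxel's positive correlations on the tau grid."""

    tau: np.ndarray
    survival: np.ndarray
    n_positive: int

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.float64)
        self.survival = np.asarray(self.survival, dtype=np.float64)
        if self.tau.shape != self.survival.shape:
            raise ValueError("tau and survival must have the same length")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.survival.min() < -1e-12 or self.survival.max() > 1 + 1e-12:
            raise ValueError("survival values must lie in [0, 1]")


@dataclass
class ICDFit:
    alpha: float
    beta: float
    rss: float
    success: bool


@dataclass
class ICDMaps:
    """Per-subject voxel-wise ICD parameter maps over the gray-matter mask.

    Failed voxels carry NaN in the parameter maps and False in ``valid``.
    """

    alpha: np.ndarray  # 3D, NaN outside mask / on failure
    beta: np.ndarray
    rss: np.ndarray
    n_positive: np.ndarray  # int counts, 0 outside mask
    valid: np.ndarray  # bool
    affine: np.ndarray


def survival_from_correlations(r: np.ndarray, tau: np.ndarray = TAU_GRID) -> SurvivalCurve | None:
    """Survival curve of the positive entries of ``r`` (strict exceedance).

    Returns None when there are no positive correlations.
    """
    r = np.asarray(r, dtype=np.float64)
    pos = np.sort(r[r > 0])
    if pos.size == 0:
        return None
    n_le = np.searchsorted(pos, tau, side="right")
    surv = 1.0 - n_le / pos.size
    return SurvivalCurve(tau, surv, int(pos.size))


def voxel_correlations(vol: Volume4D, gm_mask: Mask3D, voxel: tuple[int, int, int],
                       tau: np.ndarray = TAU_GRID) -> SurvivalCurve | None:
    """Survival curve of one voxel's positive correlations to all other
    gray-matter voxels (retained frames only)."""
    ts = vol.data[gm_mask.data][:, vol.retained_frames]
    idx_map = -np.ones(gm_mask.data.shape, dtype=int)
    idx_map[gm_mask.data] = np.arange(gm_mask.n_voxels)
    i = idx_map[voxel]
    if i < 0:
        raise ValueError(f"voxel {voxel} is not inside the gray-matter mask")
    z = _standardize_rows(ts)
    if z is None or not np.isfinite(z[i]).all():
        return None
    if z[i].std() == 0:
        return None
    r = (z @ z[i]) / z.shape[1]
    r = np.delete(r, i)
    return survival_from_correlations(r, tau)


def _standardize_rows(ts: np.ndarray) -> np.ndarray | None:
    ts = ts - ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ts / sd
    z[~np.isfinite(z)] = np.nan
    return z


def _linearized_init(tau: np.ndarray, surv: np.ndarray) -> tuple[float, float]:
    """Initial (alpha, beta) from the log-log linearization
    log(-log S) = beta log alpha + beta log tau on interior points."""
    inside = (surv > 1e-9) & (surv < 1 - 1e-9)
    if inside.sum() < 2:
        return 1.0, 1.0
    y = np.log(-np.log(surv[inside]))
    x = np.log(tau[inside])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return 1.0, 1.0
    beta = float(np.clip(slope, 0.05, 20.0))
    alpha = float(np.clip(np.exp(intercept / slope), 1e-3, 1e3))
    return alpha, beta


def fit_icd(curve: SurvivalCurve, xtol: float = 1e-12, ftol: float = 1e-12) -> ICDFit:
    """Nonlinear least squares of the stretched-exponential survival model.

    Parameters are optimized in log space (hence positive by
    construction), starting from the log-log linearization; if that fit
    fails to converge, a small restart lattice over (alpha, beta) is
    tried and the best residual kept.  Curves with fewer than five
    interior points (survival strictly between 0 and 1) carry no decay
    information and are marked failed.
    """
    tau, surv = curve.tau, curve.survival
    interior = int(np.sum((surv > 0) & (surv < 1)))
    if interior < MIN_INTERIOR_POINTS:
        return ICDFit(np.nan, np.nan, np.nan, False)

    def resid(logp: np.ndarray) -> np.ndarray:
        return icd_model(tau, np.exp(logp[0]), np.exp(logp[1])) - surv

    def run(a0: float, b0: float):
        return least_squares(resid, x0=[np.log(a0), np.log(b0)], method="lm",
                             xtol=xtol, ftol=ftol, gtol=1e-12, max_nfev=400)

    best = run(*_linearized_init(tau, surv))
    best_rss = float(np.sum(best.fun**2))
    if not best.success:
        for a0 in ALPHA_RESTARTS:
            for b0 in BETA_RESTARTS:
                sol = run(a0, b0)
                rss = float(np.sum(sol.fun**2))
                if sol.success and rss < best_rss - 1e-15:
                    best, best_rss = sol, rss
    if not best.success:
        return ICDFit(np.nan, np.nan, np.nan, False)
    return ICDFit(float(np.exp(best.x[0])), float(np.exp(best.x[1])), best_rss, True)


def grid_search_icd(curve: SurvivalCurve, alphas: np.ndarray, betas: np.ndarray
                    ) -> tuple[float, float, float]:
    """Brute-force (alpha, beta) lattice minimizer of the same objective.

    Used as an independent check that the gradient-based fit reaches the
    global optimum; never used as the estimator.
    """
    best = (np.nan, np.nan, np.inf)
    for a in alphas:
        for b in betas:
            rss = float(np.sum((icd_model(curve.tau, a, b) - curve.survival) ** 2))
            if rss < best[2]:
                best = (float(a), float(b), rss)
    return best


def icd_subject(vol: Volume4D, gm_mask: Mask3D, tau: np.ndarray = TAU_GRID,
                chunk_size: int = 256, max_fail_frac: float = 0.20) -> ICDMaps:
    """Fit the ICD model at every gray-matter voxel.

    Correlations are computed in voxel chunks against all gray-matter
    voxels so peak memory stays bounded by ``chunk_size * n_voxels``;
    voxels are independent, so the result is identical for any chunking.
    Aborts when more than ``max_fail_frac`` of voxels fail to fit.
    """
    gm = gm_mask.data
    n_vox = int(gm.sum())
    if n_vox < 2:
        raise ValueError("gray-matter mask must contain at least 2 voxels")
    keep = vol.retained_frames
    if len(keep) < 10:
        raise ValueError(f"need >= 10 retained frames, got {len(keep)}")
    ts = vol.data[gm][:, keep]
    z = _standardize_rows(ts)
    zero_var = ~np.isfinite(z).all(axis=1)
    z[zero_var] = 0.0
    n_t = z.shape[1]

    alpha = np.full(n_vox, np.nan)
    beta = np.full(n_vox, np.nan)
    rss = np.full(n_vox, np.nan)
    n_pos = np.zeros(n_vox, dtype=int)
    valid = np.zeros(n_vox, dtype=bool)

    for start in range(0, n_vox, chunk_size):
        stop = min(start + chunk_size, n_vox)
        r_block = (z[start:stop] @ z.T) / n_t
        for i in range(start, stop):
            if zero_var[i]:
                continue
            r = np.delete(r_block[i - start], i)
            curve = survival_from_correlations(r, tau)
            if curve is None:
                continue
            n_pos[i] = curve.n_positive
            fit = fit_icd(curve)
            if fit.success:
                alpha[i], beta[i], rss[i] = fit.alpha, fit.beta, fit.rss
                valid[i] = True

    fail_frac = 1.0 - valid.mean()
    if fail_frac > max_fail_frac:
        raise RuntimeError(
            f"ICD fit failed on {100 * fail_frac:.1f}% of gray-matter voxels "
            f"(limit {100 * max_fail_frac:.0f}%)"
        )

    def to_map(vec, fill=np.nan, dtype=np.float64):
        out = np.full(gm.shape, fill, dtype=dtype)
        out[gm] = vec
        return out

    return ICDMaps(
        alpha=to_map(alpha),
        beta=to_map(beta),
        rss=to_map(rss),
        n_positive=to_map(n_pos, fill=0, dtype=np.int64),
        valid=to_map(valid, fill=False, dtype=bool),
        affine=vol.affine,
    )


def smooth_parameter_map(maps: ICDMaps, fwhm_mm: float, gm_mask: Mask3D) -> ICDMaps:
    """Mask-renormalized Gaussian smoothing of the alpha and beta maps.

    Failed voxels are excluded from the kernel normalization and stay
    NaN in the output.
    """
    valid_mask = Mask3D(gm_mask.data & maps.valid, gm_mask.affine)
    out = {}
    for name in ("alpha", "beta"):
        m = getattr(maps, name).copy()
        filled = np.where(valid_mask.data, m, 0.0)
        sm = smooth_gaussian(filled, maps.affine, fwhm_mm, valid_mask)
        out[name] = np.where(valid_mask.data, sm, np.nan)
    return ICDMaps(
        alpha=out["alpha"],
        beta=out["beta"],
        rss=maps.rss,
        n_positive=maps.n_positive,
        valid=maps.valid,
        affine=maps.affine,
    )
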