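"""Voxel-wise regression of ICD parameters on trauma exposure, with
cluster-extent correction.

Per voxel, the parameter value is regressed by OLS on: intercept, coded
TE count (0-3), sex (female = 0, male = 1), the sex x TE product, age
and maternal education.  With this coding the TE coefficient is the
female slope and the interaction coefficient is the male - female slope
difference.

Family-wise error control uses a permutation maximum-cluster-size null
(Freedman-Lane): residuals of the reduced model (tested term removed)
are permuted across subjects, the full model is refit, voxels are
re-thresholded and the largest connected component recorded.  A cluster
is significant when its corrected p — the fraction of null maxima at
least as large, with the observed dataset counted once — is at or below
the cluster alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import Mask3D
from .qc import SubjectRecord

TERM_NAMES = ("intercept", "te", "sex", "sex_x_te", "age", "maternal_education")


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable design matrices."""


def build_design(subjects: Sequence[SubjectRecord]) -> tuple[np.ndarray, list[str]]:
    """Design matrix (n x 6) in TERM_NAMES order; female = 0, male = 1."""
    rows = []
    for s in subjects:
        if s.te_coded is None or s.maternal_education is None:
            raise DesignError(f"subject {s.subject_id} has missing covariates (QC should have excluded)")
        male = 1.0 if s.sex == "male" else 0.0
        rows.append([1.0, float(s.te_coded), male, male * s.te_coded, s.age, s.maternal_education])
    X = np.asarray(rows, dtype=np.float64)
    if X.shape[0] < 10:
        raise DesignError(f"need >= 10 subjects, got {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError(
            f"design matrix rank {rank} < {X.shape[1]}; degenerate cohort "
            "(e.g. single sex or single TE level)"
        )
    return X, list(TERM_NAMES)


@dataclass
class VoxelGLMResult:
    """Per-term, per-voxel OLS output over the flattened voxel axis."""

    coef: np.ndarray  # (n_terms, V)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    terms: list[str]

    def term_index(self, term: str) -> int:
        return self.terms.index(term)


def fit_voxelwise(Y: np.ndarray, X: np.ndarray,
                  terms: Sequence[str] = TERM_NAMES) -> VoxelGLMResult:
    """OLS of every column of ``Y`` (subjects x voxels) on ``X``."""
    Y = np.asarray(Y, dtype=np.float64)
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"Y has {Y.shape[0]} rows but design has {n}")
    df = n - k
    if df < 1:
        raise DesignError("non-positive residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    coef = pinv @ Y
    resid = Y - X @ coef
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 1.0)
    return VoxelGLMResult(coef=coef, se=se, t=t, p=p, df=df, terms=list(terms))


def interaction_slopes(result: VoxelGLMResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (male_slope, female_slope) of the parameter vs TE count.

    Requires female = 0 coding: the TE coefficient is the female slope
    and male slope = TE + interaction coefficients.
    """
    te = result.coef[result.term_index("te")]
    inter = result.coef[result.term_index("sex_x_te")]
    return te + inter, te


@dataclass
class Cluster:
    """A corrected supra-threshold connected component."""

    cluster_id: int
    voxels: np.ndarray  # (k, 3) voxel indices
    size: int
    peak_voxel_index: tuple[int, int, int]
    peak_voxel_mm: tuple[float, float, float]
    average_effect_size: float
    corrected_p: float
    hemisphere: str


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _max_cluster_size(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _t_for_term(Y: np.ndarray, X: np.ndarray, j: int, pinv: np.ndarray,
                cjj: float, df: int) -> np.ndarray:
    coef = pinv @ Y
    resid = Y - X @ coef
    sigma2 = np.sum(resid**2, axis=0) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        return coef[j] / np.sqrt(cjj * sigma2)


def cluster_correct(
    Y: np.ndarray,
    X: np.ndarray,
    term: str,
    gm_mask: Mask3D,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 6,
    terms: Sequence[str] = TERM_NAMES,
) -> tuple[list[Cluster], dict]:
    """Permutation cluster-extent correction for one model term.

    ``Y`` is subjects x gray-matter voxels (column order = C-order scan
    of the mask).  Returns the significant clusters and an info dict
    with the null distribution and observed cluster inventory.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    terms = list(terms)
    j = terms.index(term)
    n, k = X.shape
    df = n - k
    structure = _connectivity_structure(connectivity)
    gm = gm_mask.data
    if Y.shape[1] != int(gm.sum()):
        raise ValueError("Y columns must match gray-matter voxel count")

    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    cjj = xtx_inv[j, j]
    t_crit = stats.t.isf(voxel_p / 2.0, df)  # two-sided voxel threshold

    t_obs = _t_for_term(Y, X, j, pinv, cjj, df)
    coef_obs = (pinv @ Y)[j]
    supra = np.zeros(gm.shape, dtype=bool)
    supra[gm] = np.abs(t_obs) > t_crit
    labels, n_clusters = ndimage.label(supra, structure=structure)

    # Freedman-Lane null of the maximum cluster size.  With the permuted
    # response Y* = F + P R (F the reduced-model fit, R its residuals),
    # F lies in the full model's column space, so the full-model fit of
    # Y* satisfies coef = pinv F + pinv (P R) and
    # RSS = ||P R||^2 - ||proj(P R)||^2, where ||P R||^2 is permutation-
    # invariant; only one (k x n)(n x V) product is needed per draw.
    Xr = np.delete(X, j, axis=1)
    pinv_r = np.linalg.inv(Xr.T @ Xr) @ Xr.T
    fitted_r = Xr @ (pinv_r @ Y)
    resid_r = Y - fitted_r
    pinv_fitted_j = (pinv @ fitted_r)[j]
    r2 = np.sum(resid_r**2, axis=0)
    XtX = X.T @ X
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    perm_supra = np.zeros(gm.shape, dtype=bool)
    for b in range(n_perm):
        perm = rng.permutation(n)
        A = pinv @ resid_r[perm]
        coef_b = pinv_fitted_j + A[j]
        rss_b = np.maximum(r2 - np.einsum("iv,iv->v", A, XtX @ A), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_b = coef_b / np.sqrt(cjj * rss_b / df)
        perm_supra[gm] = np.abs(t_b) > t_crit
        null_max[b] = _max_cluster_size(perm_supra, structure)

    clusters: list[Cluster] = []
    all_sizes: list[int] = []
    coef_map = np.zeros(gm.shape)
    coef_map[gm] = coef_obs
    center_mm = (np.asarray(gm.shape) / 2.0) @ np.asarray(gm_mask.affine)[:3, :3].T
    for cid in range(1, n_clusters + 1):
        vox = np.argwhere(labels == cid)
        size = len(vox)
        all_sizes.append(size)
        corrected_p = (1 + int(np.sum(null_max >= size))) / (n_perm + 1)
        if corrected_p > cluster_alpha:
            continue
        vals = np.abs(coef_map[vox[:, 0], vox[:, 1], vox[:, 2]])
        # peak = largest |coefficient|; ties broken by smallest linear index
        peak = vox[int(np.argmax(vals))]
        peak_mm = np.asarray(gm_mask.affine) @ np.array([*peak, 1.0])
        clusters.append(
            Cluster(
                cluster_id=len(clusters) + 1,
                voxels=vox,
                size=size,
                peak_voxel_index=tuple(int(v) for v in peak),
                peak_voxel_mm=tuple(float(v) for v in peak_mm[:3]),
                average_effect_size=float(
                    coef_map[vox[:, 0], vox[:, 1], vox[:, 2]].mean()
                ),
                corrected_p=float(corrected_p),
                hemisphere="left" if peak_mm[0] < center_mm[0] else "right",
            )
        )
    clusters.sort(key=lambda c: -c.size)
    for i, c in enumerate(clusters):
        c.cluster_id = i + 1
    info = {
        "term": term,
        "t_crit": float(t_crit),
        "null_max_sizes": null_max,
        "size_threshold": float(np.quantile(null_max, 1 - cluster_alpha)) if n_perm else np.nan,
        "observed_sizes": all_sizes,
        "n_perm": n_perm,
        "seed": seed,
        "connectivity": connectivity,
    }
    return clusters, info


def cluster_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Cluster inventory table (id, size, hemisphere, peak mm, average
    effect size, corrected p)."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "size_voxels": c.size,
            "hemisphere": c.hemisphere,
            "peak_x_mm": c.peak_voxel_mm[0],
            "peak_y_mm": c.peak_voxel_mm[1],
            "peak_z_mm": c.peak_voxel_mm[2],
            "average_effect_size": c.average_effect_size,
            "corrected_p": c.corrected_p,
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size_voxels", "hemisphere", "peak_x_mm", "peak_y_mm",
            "peak_z_mm", "average_effect_size", "corrected_p",
        ],
    )
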