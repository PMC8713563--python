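"""Seed-based network definition and reference-parcellation overlap.

A significant cluster serves as a seed: each subject's seed-mean time
series is correlated with every gray-matter voxel and Fisher
z-transformed.  A one-sample t-test across subjects, thresholded
jointly on p and Benjamini-Hochberg FDR q (and, by default, restricted
to positive mean z), defines the network.  Networks are scored by the
percentage of their voxels carrying each of the 7 reference-parcellation
labels, plus directional pairwise overlaps between constructed networks.

The default thresholds (p < 1e-44, FDR < 3e-16) presume a very large
cohort; at desk-scale sample sizes callers must pass attainable values
(e.g. p < 1e-6, q < 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .images import Mask3D, Parcellation3D, Volume4D, same_grid

Z_CLIP = 1.0 - 1e-7  # |r| clip before atanh


class SeedError(RuntimeError):
    """Raised when a subject's seed time series is unusable (constant)."""


def seed_connectivity(vol: Volume4D, seed_voxels: np.ndarray, gm_mask: Mask3D) -> np.ndarray:
    """Fisher-z map of one subject's correlation with the seed-mean series.

    ``seed_voxels`` is a (k, 3) voxel-index array.  Returns a 3D map
    (NaN outside gray matter).
    """
    keep = vol.retained_frames
    seed_ts = vol.data[seed_voxels[:, 0], seed_voxels[:, 1], seed_voxels[:, 2]][:, keep].mean(axis=0)
    if seed_ts.std() == 0:
        raise SeedError("seed time series is constant")
    ts = vol.data[gm_mask.data][:, keep]
    ts = ts - ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1)
    seed_c = seed_ts - seed_ts.mean()
    denom = sd * seed_c.std() * len(keep)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ts @ seed_c) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    out = np.full(gm_mask.data.shape, np.nan)
    out[gm_mask.data] = z
    return out


@dataclass
class NetworkMap:
    """Group-level seed network with per-voxel statistics."""

    mean_z: np.ndarray  # 3D
    t_map: np.ndarray
    p_map: np.ndarray
    fdr_q_map: np.ndarray
    network_mask: np.ndarray  # bool 3D
    n_voxels: int
    affine: np.ndarray


def group_network(
    z_maps: Sequence[np.ndarray],
    gm_mask: Mask3D,
    p_thresh: float = 1e-44,
    fdr_thresh: float = 3e-16,
    positive_only: bool = True,
) -> NetworkMap:
    """One-sample t-test of Fisher-z maps against 0, with joint p/FDR
    thresholding, defining a resting-state network."""
    if len(z_maps) < 2:
        raise ValueError("group_network needs at least 2 subjects")
    gm = gm_mask.data
    Z = np.stack([np.asarray(z)[gm] for z in z_maps], axis=0)  # (n, V)
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(zero_var, 1.0, p)  # degenerate voxels never pass
    t = np.where(zero_var, 0.0, t)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    mask_flat = (p < p_thresh) & (q < fdr_thresh)
    if positive_only:
        mask_flat &= mean > 0

    def to_map(v, fill=np.nan):
        out = np.full(gm.shape, fill)
        out[gm] = v
        return out

    net = np.zeros(gm.shape, dtype=bool)
    net[gm] = mask_flat
    return NetworkMap(
        mean_z=to_map(mean),
        t_map=to_map(t),
        p_map=to_map(p, fill=1.0),
        fdr_q_map=to_map(q, fill=1.0),
        network_mask=net,
        n_voxels=int(mask_flat.sum()),
        affine=gm_mask.affine,
    )


@dataclass
class OverlapProfile:
    """Percentage of network voxels carrying each reference label."""

    percentages: dict[int, float]  # label -> % of network voxels
    unlabeled_pct: float
    n_voxels: int

    def __post_init__(self) -> None:
        total = sum(self.percentages.values()) + self.unlabeled_pct
        if self.n_voxels and abs(total - 100.0) > 1e-9:
            raise ValueError(f"overlap percentages sum to {total}, not 100")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reference_label": lab, "pct_overlap": pct}
            for lab, pct in sorted(self.percentages.items())
        ]
        rows.append({"reference_label": 0, "pct_overlap": self.unlabeled_pct})
        return pd.DataFrame(rows)


def overlap_with_reference(net: NetworkMap, parc: Parcellation3D) -> OverlapProfile:
    """Label composition of a network against the 7-label reference."""
    same_grid(
        Mask3D(net.network_mask, net.affine), parc
    )
    labels = parc.data[net.network_mask]
    n = labels.size
    pct = {}
    for lab in range(1, parc.n_labels + 1):
        pct[lab] = 100.0 * np.count_nonzero(labels == lab) / n if n else 0.0
    unlabeled = 100.0 * np.count_nonzero(labels == 0) / n if n else 0.0
    return OverlapProfile(percentages=pct, unlabeled_pct=unlabeled, n_voxels=n)


def pairwise_overlap(a_mask: np.ndarray, b_mask: np.ndarray) -> float:
    """Percentage of network B's voxels contained in network A:
    |A intersect B| / |B| * 100."""
    b_n = int(np.count_nonzero(b_mask))
    if b_n == 0:
        return 0.0
    return 100.0 * int(np.count_nonzero(a_mask & b_mask)) / b_n


def dice(a_mask: np.ndarray, b_mask: np.ndarray) -> float:
    """Dice coefficient between two binary masks."""
    a_n = int(np.count_nonzero(a_mask))
    b_n = int(np.count_nonzero(b_mask))
    if a_n + b_n == 0:
        return 0.0
    return 2.0 * int(np.count_nonzero(a_mask & b_mask)) / (a_n + b_n)
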