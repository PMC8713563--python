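"""Light-weight gridded image containers and NIfTI I/O.

All images in one analysis share a single affine and grid shape; the
containers here enforce that contract and delegate serialization to
nibabel.  No resampling is implemented: inputs must already live on a
common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume4D",
    "Mask3D",
    "Parcellation3D",
    "make_affine",
    "voxel_sizes",
    "load_volume4d",
    "load_mask",
    "load_parcellation",
    "save_nifti",
]


def make_affine(voxel_size_mm: float) -> np.ndarray:
    """Diagonal voxel-to-mm affine with isotropic voxels and origin at 0."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (norm of the affine columns)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass
class Volume4D:
    """A 4D BOLD series on an (x, y, z, t) grid.

    ``censored_frames`` is the set of frame indices excluded from every
    regression and correlation downstream; censored frames stay in the
    array (zeroed after nuisance regression) so indices remain stable.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    censored_frames: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires 4D data, got {self.data.ndim}D")
        bad = [i for i in self.censored_frames if not 0 <= i < self.n_frames]
        if bad:
            raise ValueError(f"censored frame indices out of range: {bad}")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def retained_frames(self) -> np.ndarray:
        """Sorted indices of non-censored frames."""
        keep = np.ones(self.n_frames, dtype=bool)
        if self.censored_frames:
            keep[sorted(self.censored_frames)] = False
        return np.flatnonzero(keep)

    @property
    def censor_fraction(self) -> float:
        return len(self.censored_frames) / self.n_frames

    def retained_data(self) -> np.ndarray:
        """Data restricted to non-censored frames, shape (x, y, z, t_kept)."""
        return self.data[..., self.retained_frames]


@dataclass
class Mask3D:
    """Binary 3D mask sharing the cohort grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("Mask3D requires 3D data")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(k, 3) array of in-mask voxel indices in C order."""
        return np.argwhere(self.data)


@dataclass
class Parcellation3D:
    """Integer-labeled reference parcellation; 0 = unlabeled, labels 1..7."""

    data: np.ndarray
    affine: np.ndarray
    n_labels: int = 7

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.int32)
        if self.data.ndim != 3:
            raise ValueError("Parcellation3D requires 3D data")
        if self.data.min() < 0 or self.data.max() > self.n_labels:
            raise ValueError(
                f"labels must lie in 0..{self.n_labels}, got "
                f"[{self.data.min()}, {self.data.max()}]"
            )


def _check_same_grid(affine_a: np.ndarray, affine_b: np.ndarray) -> None:
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise ValueError("affines differ; all inputs must share one grid")


def same_grid(a, b) -> None:
    """Raise if two containers do not share affine and 3D shape."""
    _check_same_grid(a.affine, b.affine)
    sa = a.data.shape[:3]
    sb = b.data.shape[:3]
    if sa != sb:
        raise ValueError(f"grid shapes differ: {sa} vs {sb}")


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    nib.save(img, str(path))


def load_volume4d(path, tr_seconds: float) -> Volume4D:
    img = nib.load(str(path))
    return Volume4D(np.asarray(img.dataobj, dtype=np.float64), img.affine, tr_seconds)


def load_mask(path) -> Mask3D:
    img = nib.load(str(path))
    return Mask3D(np.asarray(img.dataobj) > 0, img.affine)


def load_parcellation(path, n_labels: int = 7) -> Parcellation3D:
    img = nib.load(str(path))
    return Parcellation3D(
        np.rint(np.asarray(img.dataobj)).astype(np.int32), img.affine, n_labels
    )
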