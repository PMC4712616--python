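"""Image containers shared by every pipeline stage.

Two carriers cover all data in the pipeline: :class:`VolumeImage` for 3D
scalar grids (structural images, masks, quantitative maps) and
:class:`TimeSeriesImage` for 4D dynamic-susceptibility-contrast (DSC)
acquisitions.  Both hold a 4x4 voxel-to-world affine in millimetres, RAS
orientation, 0-based voxel indices.  NIfTI round-trips go through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "TimeSeriesImage", "load_volume", "load_series"]


def _voxel_sizes(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel->world (mm) affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> world-mm mapping.
    space : str
        Label of the coordinate space (e.g. ``"flair"``, ``"t1"``).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("VolumeImage requires a non-empty 3D grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.allclose(self.affine[3], [0, 0, 0, 1]):
            raise ValueError("affine last row must be (0, 0, 0, 1)")
        if np.any(self.voxel_mm <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_mm(self) -> np.ndarray:
        """Per-axis voxel size in mm, derived from the affine."""
        return _voxel_sizes(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray, space: str | None = None) -> "VolumeImage":
        """New volume on this grid with different data."""
        return replace(self, data=np.asarray(data), space=space or self.space)

    def same_grid(self, other: "VolumeImage") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.affine)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        nib.save(self.to_nifti(), str(path))
        return path


@dataclass
class TimeSeriesImage:
    """A 4D (x, y, z, t) acquisition with repetition/echo times in seconds."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr_s: float = 1.0
    te_s: float = 0.03
    space: str = "dsc"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("TimeSeriesImage requires 4D (x,y,z,t) data")
        if self.tr_s <= 0 or self.te_s <= 0:
            raise ValueError("tr_s and te_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_s

    def frame(self, t: int) -> VolumeImage:
        return VolumeImage(self.data[..., t], self.affine, space=self.space)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(np.asarray(self.data), self.affine)
        img.header["pixdim"][4] = self.tr_s
        nib.save(img, str(path))
        return path


def load_volume(path: str | Path, space: str = "unknown") -> VolumeImage:
    img = nib.load(str(path))
    return VolumeImage(np.asanyarray(img.dataobj), img.affine, space=space)


def load_series(path: str | Path, tr_s: float | None = None,
                te_s: float = 0.03) -> TimeSeriesImage:
    img = nib.load(str(path))
    if tr_s is None:
        tr_s = float(img.header["pixdim"][4]) or 1.0
    return TimeSeriesImage(np.asanyarray(img.dataobj), img.affine,
                           tr_s=tr_s, te_s=te_s)
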