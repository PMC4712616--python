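"""Affine spatial transforms: estimation, resampling, mask transfer.

Registration here is deliberately simple: a 6-degree-of-freedom rigid
transform (3 rotations, 3 translations) estimated by multi-resolution Powell
search over a normalized-mutual-information metric.  The estimator is
pluggable — any callable returning an :class:`AffineTransform` can stand in —
because in this pipeline registration is a solved backend choice, not the
scientific contribution.

Conventions: world coordinates in mm, RAS; voxel indices 0-based; transforms
map *moving*-space world coordinates to *fixed*-space world coordinates.
Labels and binary masks are always resampled nearest-neighbour (preserves the
value set); quantitative maps linearly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .image import VolumeImage

__all__ = ["AffineTransform", "estimate_rigid", "resample", "apply_to_mask",
           "rigid_matrix", "is_near_identity"]


@dataclass
class AffineTransform:
    """4x4 homogeneous world->world (mm) mapping between two named spaces."""

    matrix: np.ndarray
    source_space: str = "moving"
    target_space: str = "fixed"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("transform last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform matrix must be invertible")

    @classmethod
    def identity(cls, source_space: str = "moving", target_space: str = "fixed"):
        return cls(np.eye(4), source_space, target_space)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix),
                               self.target_space, self.source_space)

    def compose(self, first: "AffineTransform") -> "AffineTransform":
        """Transform applying ``first`` then ``self``."""
        return AffineTransform(self.matrix @ first.matrix,
                               first.source_space, self.target_space)

    def save(self, path: str | Path) -> Path:
        """Plain-text row-major 4x4 matrix, space labels in a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.matrix, fmt="%.12g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"source_space": self.source_space, "target_space": self.target_space}))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        path = Path(path)
        matrix = np.loadtxt(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        labels = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(matrix, labels.get("source_space", "moving"),
                   labels.get("target_space", "fixed"))


def is_near_identity(transform: AffineTransform, fov: VolumeImage,
                     tol_mm: float = 0.1) -> bool:
    """True when the transform moves no corner of ``fov`` by more than tol.

    Such transforms sit below the estimator's resolution; resampling through
    them only adds interpolation blur, so callers snap them to the identity.
    """
    nx, ny, nz = fov.shape
    corners = np.array([[x, y, z, 1.0] for x in (0, nx - 1)
                        for y in (0, ny - 1) for z in (0, nz - 1)]).T
    world = fov.affine @ corners
    moved = transform.matrix @ world
    return bool(np.linalg.norm((moved - world)[:3], axis=0).max() <= tol_mm)


def rigid_matrix(angles_rad: np.ndarray, translation_mm: np.ndarray,
                 center_mm: np.ndarray) -> np.ndarray:
    """Rigid 4x4: rotate by (rx, ry, rz) about ``center_mm``, then translate."""
    rx, ry, rz = angles_rad
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    r_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    r_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    r_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = r_z @ r_y @ r_x
    mat = np.eye(4)
    mat[:3, :3] = rot
    mat[:3, 3] = np.asarray(center_mm) - rot @ np.asarray(center_mm) + np.asarray(translation_mm)
    return mat


def _voxel_matrix(image: VolumeImage, transform: AffineTransform,
                  target: VolumeImage) -> np.ndarray:
    """Voxel->voxel pullback matrix for scipy.ndimage.affine_transform."""
    return (np.linalg.inv(image.affine)
            @ np.linalg.inv(transform.matrix)
            @ target.affine)


def resample(image: VolumeImage, transform: AffineTransform,
             target: VolumeImage, interp: str = "linear") -> VolumeImage:
    """Resample ``image`` onto ``target``'s grid under a world transform.

    ``interp`` is ``"linear"`` (quantitative maps) or ``"nearest"`` (labels,
    masks).  Voxels mapping outside the source field of view become 0.
    """
    orders = {"linear": 1, "nearest": 0}
    if interp not in orders:
        raise ValueError(f"interp must be one of {sorted(orders)}, got {interp!r}")
    mvox = _voxel_matrix(image, transform, target)
    out = ndimage.affine_transform(
        np.asarray(image.data, dtype=float), mvox[:3, :3], offset=mvox[:3, 3],
        output_shape=target.shape, order=orders[interp], mode="constant", cval=0.0)
    if interp == "nearest":
        out = out.astype(image.data.dtype)
    return VolumeImage(out, target.affine, space=target.space)


def apply_to_mask(mask: VolumeImage, transform: AffineTransform,
                  target: VolumeImage) -> VolumeImage:
    """Carry a binary mask across spaces with an already-estimated transform.

    This is how a FLAIR-space lesion mask reaches the T1 grid: the FLAIR–T1
    transform is reused unchanged, never re-estimated on the mask itself.
    """
    vals = np.unique(np.asarray(mask.data))
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("apply_to_mask requires a binary {0,1} mask")
    out = resample(mask.like(mask.data.astype(np.uint8)), transform, target,
                   interp="nearest")
    return VolumeImage(out.data.astype(np.uint8), target.affine, space=target.space)


# ---------------------------------------------------------------------------
# Built-in rigid estimator
# ---------------------------------------------------------------------------

def _nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) over joint histogram."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def entropy(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p))

    hxy = entropy(pxy.ravel())
    if hxy == 0:
        return 2.0
    return (entropy(px) + entropy(py)) / hxy


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return -float(np.mean((a - b) ** 2))


def _downsample(image: VolumeImage, factor: int) -> VolumeImage:
    if factor == 1:
        return image
    data = ndimage.gaussian_filter(np.asarray(image.data, dtype=float), factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    aff = image.affine.copy()
    aff[:3, :3] *= factor
    return VolumeImage(data, aff, space=image.space)


def _world_com(image: VolumeImage) -> np.ndarray:
    data = np.asarray(image.data, dtype=float)
    data = data - data.min()
    com_vox = ndimage.center_of_mass(data)
    return (image.affine @ np.array([*com_vox, 1.0]))[:3]


@dataclass
class RigidOptions:
    """Knobs of the built-in estimator."""

    metric: str = "nmi"               # "nmi" (cross-modality) or "mse"
    levels: tuple[int, ...] = (4, 2, 1)
    bins: int = 32
    xtol: float = 1e-4
    maxiter: int = 40
    init_translation: bool = True     # centre-of-mass seeding
    scale_rot: float = 100.0          # mm-equivalent scaling of angles
    _extra: dict = field(default_factory=dict)


def estimate_rigid(moving: VolumeImage, fixed: VolumeImage,
                   opts: RigidOptions | None = None) -> AffineTransform:
    """Estimate the 6-DOF rigid transform mapping moving->fixed world space.

    Deterministic given inputs and options.  Raises on constant images, for
    which every intensity metric is undefined.
    """
    opts = opts or RigidOptions()
    for name, img in (("moving", moving), ("fixed", fixed)):
        if np.ptp(np.asarray(img.data, dtype=float)) == 0:
            raise ValueError(f"estimate_rigid: {name} image is constant; metric undefined")
    metric = {"nmi": lambda a, b: _nmi(a, b, opts.bins), "mse": _mse}[opts.metric]
    center = (fixed.affine @ np.array([(fixed.shape[0] - 1) / 2,
                                       (fixed.shape[1] - 1) / 2,
                                       (fixed.shape[2] - 1) / 2, 1.0]))[:3]

    params = np.zeros(6)  # (rx, ry, rz) scaled, (tx, ty, tz) mm
    if opts.init_translation:
        params[3:] = _world_com(fixed) - _world_com(moving)

    fixed_arr_cache: dict[int, VolumeImage] = {}
    moving_cache: dict[int, VolumeImage] = {}

    def cost(p, level):
        mat = rigid_matrix(p[:3] / opts.scale_rot, p[3:], center)
        tr = AffineTransform(mat, moving.space, fixed.space)
        fx = fixed_arr_cache[level]
        mv = moving_cache[level]
        res = resample(mv, tr, fx, interp="linear")
        return -metric(np.asarray(fx.data, dtype=float), res.data)

    for level in opts.levels:
        fixed_arr_cache[level] = _downsample(fixed, level)
        moving_cache[level] = _downsample(moving, level)
        best = cost(params, level)
        result = optimize.minimize(
            cost, params, args=(level,), method="Powell",
            options={"xtol": opts.xtol, "ftol": 1e-9,
                     "maxiter": opts.maxiter * 6, "maxfev": 4000})
        # keep the incoming parameters when the search did not improve on
        # them (Powell always perturbs, even off a perfect optimum)
        if result.fun < best:
            params = result.x

    mat = rigid_matrix(params[:3] / opts.scale_rot, params[3:], center)
    return AffineTransform(mat, moving.space, fixed.space)
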