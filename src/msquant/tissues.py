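"""Normal-appearing tissue masks and volume normalization.

"Normal-appearing" grey/white matter (NAGM/NAWM) is tissue outside visible
lesions: the registered lesion mask is subtracted voxelwise from the GM and
WM masks.  Deep grey structures (caudate, putamen, globus pallidus,
thalamus, left/right) are accepted as external label inputs.  When no
external segmentation exists — e.g. on phantoms — a fallback 3-class
intensity clustering of the T1 image stands in, with classes ordered by
mean intensity and mapped CSF < GM < WM (T1 contrast).  Regional volumes
can be normalized by a skull-size scaling factor supplied as input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .image import VolumeImage
from .phantom import DEEP_STRUCTURES, TISSUE_CODES

__all__ = ["TissueLabels", "make_normal_appearing", "fallback_tissue_segmentation",
           "normalized_volume"]


@dataclass
class TissueLabels:
    """A label volume plus its code table (written as a JSON sidecar)."""

    labels: VolumeImage
    code_table: dict[str, int] = field(default_factory=lambda: dict(TISSUE_CODES))

    def __post_init__(self) -> None:
        present = set(np.unique(np.asarray(self.labels.data))) - {0}
        known = set(self.code_table.values())
        missing = present - known
        if missing:
            raise ValueError(f"labels present but not in code table: {sorted(missing)}")
        if len(set(self.code_table.values())) != len(self.code_table):
            raise ValueError("code table values must be disjoint")

    def mask(self, name: str) -> VolumeImage:
        code = self.code_table[name]
        return self.labels.like((np.asarray(self.labels.data) == code).astype(np.uint8))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.labels.save(path)
        name = path.name.removesuffix(".nii.gz").removesuffix(".nii")
        (path.parent / f"{name}_codes.json").write_text(json.dumps(self.code_table, indent=2))
        return path


def _require_binary(name: str, img: VolumeImage) -> np.ndarray:
    arr = np.asarray(img.data)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError(f"{name} must be a binary mask")
    return arr.astype(bool)


def make_normal_appearing(gm_mask: VolumeImage, wm_mask: VolumeImage,
                          lesion_mask: VolumeImage) -> tuple[VolumeImage, VolumeImage]:
    """NAGM = GM ∧ ¬lesion, NAWM = WM ∧ ¬lesion (all on one grid)."""
    if not (gm_mask.same_grid(wm_mask) and gm_mask.same_grid(lesion_mask)):
        raise ValueError("gm/wm/lesion masks must share a grid")
    gm = _require_binary("gm_mask", gm_mask)
    wm = _require_binary("wm_mask", wm_mask)
    lesion = _require_binary("lesion_mask", lesion_mask)
    nagm = gm & ~lesion
    nawm = wm & ~lesion
    return (gm_mask.like(nagm.astype(np.uint8)), wm_mask.like(nawm.astype(np.uint8)))


def fallback_tissue_segmentation(t1: VolumeImage, brain_mask: VolumeImage,
                                 seed: int = 0) -> TissueLabels:
    """3-class intensity clustering of T1 inside the brain mask.

    K-means on the scalar intensities, clusters sorted by mean and mapped to
    CSF < GM < WM (the T1 contrast ordering).  Deterministic given ``seed``;
    invariant to positive affine intensity rescaling (intensities are
    standardized before clustering).
    """
    mask = _require_binary("brain_mask", brain_mask)
    if not mask.any():
        raise ValueError("brain mask is empty")
    values = np.asarray(t1.data, dtype=float)[mask]
    if np.ptp(values) == 0:
        raise ValueError("T1 is constant inside the mask; clustering undefined")
    standardized = (values - values.mean()) / values.std()
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    assignments = km.fit_predict(standardized.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(3, dtype=np.int16)
    remap[order] = [TISSUE_CODES["csf"], TISSUE_CODES["gm"], TISSUE_CODES["wm"]]
    labels = np.zeros(t1.shape, dtype=np.int16)
    labels[mask] = remap[assignments]
    table = dict(TISSUE_CODES)
    table.update(DEEP_STRUCTURES)
    return TissueLabels(t1.like(labels), code_table=table)


def normalized_volume(volume_mm3: float, vscale: float = 1.0) -> float:
    """Skull-size normalization: volume × scaling factor."""
    if vscale <= 0:
        raise ValueError("vscale must be > 0")
    return volume_mm3 * vscale
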