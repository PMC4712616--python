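"""Lesion segmentation, NAWM-referenced classification, and ROI files.

MS lesions are first delineated on FLAIR (where they are hyperintense) by a
seeded, local-threshold region growing; a reference region of
normal-appearing white matter (NAWM) is outlined separately.  Each lesion is
then classified from its mean intensity on the registered non-enhanced T1
and Gd-enhanced T1 images against two thresholds derived from the NAWM
statistics of each modality:

    Thre_High = Ī + Mf · SD(I_NAWM)
    Thre_Low  = Ī − Mf · SD(I_NAWM)

where Ī and SD are the NAWM ROI mean and sample standard deviation and Mf a
configurable multiplier (default 2.0).  A lesion is *enhancing* when its
Gd-T1 mean exceeds the Gd-T1 Thre_High, and *hypointense* when its T1 mean
falls below the T1 Thre_Low; the four combinations give classes C1–C4:

    C1 enhancing / isointense      (acute)
    C2 enhancing / hypointense     (acute)
    C3 non-enhancing / isointense  (chronic)
    C4 non-enhancing / hypointense (chronic "black hole")

Because both the lesion mean and the thresholds are affine in the image
intensities, the classification is invariant to any global rescaling
a·I + b (a > 0).

The ROI inventory round-trips through a small human-editable text dialect so
an operator can revise class codes by hand and reload the file.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import VolumeImage

__all__ = [
    "Roi", "RoiSet", "ClassThresholds", "CLASS_COLORS",
    "grow_lesion_roi", "nawm_stats", "classification_thresholds",
    "classify_lesions", "write_roiset", "read_roiset", "class_masks",
]

NAWM_REF = "NAWM_REF"
UNCLASSIFIED = "UNCLASSIFIED"
LESION_CLASSES = ("C1", "C2", "C3", "C4")
VALID_CLASSES = (NAWM_REF, UNCLASSIFIED) + LESION_CLASSES

#: display colors, one per class code (hex RGB)
CLASS_COLORS = {
    NAWM_REF: "#00c000",
    UNCLASSIFIED: "#808080",
    "C1": "#ff2020",       # acute, enhancing
    "C2": "#ff20ff",       # acute, enhancing black-hole precursor
    "C3": "#ffc020",       # chronic
    "C4": "#2020ff",       # chronic black hole
}

_FULL_CONN = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class Roi:
    """A labelled voxel region on the FLAIR grid."""

    id: int
    voxels: list[tuple[int, int, int]]
    class_code: str = UNCLASSIFIED
    label_text: str = ""
    color: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.voxels:
            raise ValueError("Roi requires at least one voxel")
        if len(set(self.voxels)) != len(self.voxels):
            raise ValueError("Roi voxels must be unique")
        if self.class_code not in VALID_CLASSES:
            raise ValueError(f"unknown class code {self.class_code!r}")
        if not self.color:
            self.color = CLASS_COLORS[self.class_code]

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = np.asarray(self.voxels)
        return idx[:, 0], idx[:, 1], idx[:, 2]

    def mean_on(self, image: VolumeImage) -> float:
        return float(np.mean(image.data[self.index_arrays()]))

    def median_on(self, image: VolumeImage) -> float:
        return float(np.median(image.data[self.index_arrays()]))

    def to_mask(self, grid: VolumeImage) -> VolumeImage:
        mask = np.zeros(grid.shape, dtype=np.uint8)
        mask[self.index_arrays()] = 1
        return grid.like(mask)


@dataclass
class RoiSet:
    """The lesion inventory: lesion ROIs plus the NAWM reference region."""

    rois: list[Roi] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def lesions(self) -> list[Roi]:
        return [r for r in self.rois if r.class_code != NAWM_REF]

    def nawm_ref(self) -> Roi | None:
        for r in self.rois:
            if r.class_code == NAWM_REF:
                return r
        return None

    def by_id(self, roi_id: int) -> Roi:
        for r in self.rois:
            if r.id == roi_id:
                return r
        raise KeyError(f"no ROI with id {roi_id}")


@dataclass(frozen=True)
class ClassThresholds:
    """NAWM statistics and the derived classification window for one modality."""

    mean_nawm: float
    sd_nawm: float
    mf: float
    thre_low: float
    thre_high: float
    modality: str = "t1"

    def __post_init__(self) -> None:
        if abs(self.thre_low - (self.mean_nawm - self.mf * self.sd_nawm)) > 1e-9 * max(1.0, abs(self.mean_nawm)):
            raise ValueError("thre_low inconsistent with mean - mf*sd")
        if abs(self.thre_high - (self.mean_nawm + self.mf * self.sd_nawm)) > 1e-9 * max(1.0, abs(self.mean_nawm)):
            raise ValueError("thre_high inconsistent with mean + mf*sd")
        if self.thre_low > self.thre_high:
            raise ValueError("thre_low must not exceed thre_high")


def grow_lesion_roi(flair: VolumeImage, seed: tuple[int, int, int],
                    local_factor: float = 0.5, roi_id: int = 1) -> Roi:
    """Seeded local-threshold region growing on FLAIR.

    The threshold is ``local_factor`` times the peak intensity in the seed's
    3x3x3 neighbourhood; the ROI is the 26-connected component of
    above-threshold voxels containing the seed.  Deterministic; the seed is
    always included.  A region touching the grid boundary gets a warning
    flag rather than an error.
    """
    seed = tuple(int(s) for s in seed)
    shape = flair.shape
    if not all(0 <= s < n for s, n in zip(seed, shape)):
        raise ValueError(f"seed {seed} outside grid {shape}")
    data = np.asarray(flair.data, dtype=float)
    if data[seed] <= 0:
        raise ValueError(f"seed intensity must be > 0, got {data[seed]} at {seed}")

    lo = [max(0, s - 1) for s in seed]
    hi = [min(n, s + 2) for s, n in zip(seed, shape)]
    peak = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].max()
    threshold = local_factor * peak

    above = data >= threshold
    above[seed] = True  # numerical safety; seed is included by construction
    labels, _ = ndimage.label(above, structure=_FULL_CONN)
    region = labels == labels[seed]
    voxels = [tuple(int(v) for v in vox) for vox in np.argwhere(region)]

    warnings = []
    idx = np.argwhere(region)
    if (idx.min(axis=0) == 0).any() or (idx.max(axis=0) == np.array(shape) - 1).any():
        warnings.append("region touches grid boundary")
    return Roi(id=roi_id, voxels=voxels, class_code=UNCLASSIFIED,
               label_text=f"seed={seed} local_factor={local_factor}",
               warnings=warnings)


def nawm_stats(image: VolumeImage, nawm_roi: Roi) -> tuple[float, float]:
    """NAWM reference statistics: arithmetic mean and sample SD (n−1)."""
    if nawm_roi.class_code != NAWM_REF:
        raise ValueError("nawm_stats requires a NAWM_REF ROI")
    if nawm_roi.n_voxels < 2:
        raise ValueError("NAWM ROI needs >= 2 voxels (SD undefined)")
    values = np.asarray(image.data, dtype=float)[nawm_roi.index_arrays()]
    return float(values.mean()), float(values.std(ddof=1))


def classification_thresholds(mean: float, sd: float, mf: float,
                              modality: str = "t1") -> ClassThresholds:
    """Thre_High = mean + mf·sd, Thre_Low = mean − mf·sd."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if mf < 0:
        raise ValueError("mf must be >= 0")
    return ClassThresholds(mean_nawm=mean, sd_nawm=sd, mf=mf,
                           thre_low=mean - mf * sd, thre_high=mean + mf * sd,
                           modality=modality)


def classify_lesions(rois: RoiSet, r_t1: VolumeImage, r_gd_t1: VolumeImage,
                     nawm_roi: Roi | None = None, mf: float = 2.0,
                     statistic: str = "mean") -> RoiSet:
    """Assign C1–C4 to every lesion ROI from registered T1 / Gd-T1 intensity.

    Thresholds are computed independently per modality from the NAWM ROI.
    Comparisons are strict (> Thre_High, < Thre_Low); a lesion exactly on a
    threshold counts as isointense / non-enhancing.  A T1-hyperintense
    lesion (mean above the T1 Thre_High) has no class of its own and is
    mapped to isointense with a warning.  Lesions with no nonzero voxel in
    either registered image (out of its field of view) stay UNCLASSIFIED.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if nawm_roi is None:
        nawm_roi = rois.nawm_ref()
    if nawm_roi is None:
        raise ValueError("classification requires a NAWM reference ROI")
    if not r_t1.same_grid(r_gd_t1):
        raise ValueError("r_t1 and r_gd_t1 must share the FLAIR grid")

    thr = {mod: classification_thresholds(*nawm_stats(img, nawm_roi), mf=mf, modality=mod)
           for mod, img in (("t1", r_t1), ("gd_t1", r_gd_t1))}
    summarize = Roi.mean_on if statistic == "mean" else Roi.median_on
    nawm_voxels = set(nawm_roi.voxels)

    out = []
    for roi in rois:
        if roi.class_code == NAWM_REF:
            out.append(roi)
            continue
        warnings = list(roi.warnings)
        if nawm_voxels & set(roi.voxels):
            warnings.append("lesion overlaps the NAWM reference ROI")
        t1_vals = r_t1.data[roi.index_arrays()]
        gd_vals = r_gd_t1.data[roi.index_arrays()]
        if not np.any(t1_vals != 0) or not np.any(gd_vals != 0):
            out.append(replace(roi, class_code=UNCLASSIFIED,
                               color=CLASS_COLORS[UNCLASSIFIED],
                               label_text="unclassified: no voxels in registered image field",
                               warnings=warnings))
            continue
        t1_stat = summarize(roi, r_t1)
        gd_stat = summarize(roi, r_gd_t1)
        enhancing = gd_stat > thr["gd_t1"].thre_high
        hypointense = t1_stat < thr["t1"].thre_low
        if t1_stat > thr["t1"].thre_high:
            warnings.append("T1-hyperintense lesion mapped to isointense")
        cls = {(True, False): "C1", (True, True): "C2",
               (False, False): "C3", (False, True): "C4"}[(enhancing, hypointense)]
        activity = "acute" if cls in ("C1", "C2") else "chronic"
        label = (f"{cls} ({activity}): {statistic} t1={t1_stat:.2f} "
                 f"[{thr['t1'].thre_low:.2f},{thr['t1'].thre_high:.2f}] "
                 f"gd_t1={gd_stat:.2f} "
                 f"[{thr['gd_t1'].thre_low:.2f},{thr['gd_t1'].thre_high:.2f}] "
                 f"mf={mf}")
        out.append(replace(roi, class_code=cls, color=CLASS_COLORS[cls],
                           label_text=label, warnings=warnings))
    return RoiSet(out)


# ---------------------------------------------------------------------------
# ROI file dialect (human-editable, revision round-trip)
# ---------------------------------------------------------------------------
# One header line per ROI:
#     ROI <id> <class> <color> "<label text>"
# followed by one "x y z" 0-based voxel-index line per voxel.

def write_roiset(rois: RoiSet, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# msquant ROI file v1",
             "# ROI <id> <class> <color> \"<label>\" ; then one 'x y z' line per voxel"]
    for roi in rois:
        lines.append(f"ROI {roi.id} {roi.class_code} {roi.color} {shlex.quote(roi.label_text or '-')}")
        for x, y, z in roi.voxels:
            lines.append(f"{x} {y} {z}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_roiset(path: str | Path) -> RoiSet:
    path = Path(path)
    rois: list[Roi] = []
    header: tuple[int, str, str, str] | None = None
    voxels: list[tuple[int, int, int]] = []

    def flush(lineno: int):
        nonlocal header, voxels
        if header is None:
            return
        rid, cls, color, label = header
        if not voxels:
            raise ValueError(f"{path}:{lineno}: ROI {rid} has no voxels")
        rois.append(Roi(id=rid, voxels=voxels, class_code=cls,
                        label_text="" if label == "-" else label, color=color))
        header, voxels = None, []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("ROI "):
            flush(lineno)
            try:
                parts = shlex.split(line)
                _, rid, cls, color = parts[:4]
                label = parts[4] if len(parts) > 4 else "-"
                header = (int(rid), cls, color, label)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed ROI header: {raw!r}") from exc
            if header[1] not in VALID_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown class {header[1]!r}")
            continue
        try:
            x, y, z = (int(tok) for tok in line.split())
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 'x y z' voxel line, got {raw!r}") from exc
        if header is None:
            raise ValueError(f"{path}:{lineno}: voxel line before any ROI header")
        voxels.append((x, y, z))
    flush(lineno=-1)
    return RoiSet(rois)


def class_masks(rois: RoiSet, grid: VolumeImage) -> dict[str, VolumeImage]:
    """Binary masks: total lesion burden, one per class C1–C4, one per lesion.

    The NAWM reference ROI is excluded everywhere.  All-zero class masks are
    still emitted so downstream reports always see the full set.
    """
    masks: dict[str, np.ndarray] = {"total": np.zeros(grid.shape, dtype=np.uint8)}
    for cls in LESION_CLASSES:
        masks[cls] = np.zeros(grid.shape, dtype=np.uint8)
    for roi in rois.lesions():
        idx = roi.index_arrays()
        per = np.zeros(grid.shape, dtype=np.uint8)
        per[idx] = 1
        masks[f"lesion_{roi.id}"] = per
        masks["total"][idx] = 1
        if roi.class_code in LESION_CLASSES:
            masks[roi.class_code][idx] = 1
    return {name: grid.like(m) for name, m in masks.items()}
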