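"""End-to-end orchestration of the measuring pipeline.

Runs, per patient: registration of T1/Gd-T1 into FLAIR space → lesion
growing and four-class classification (with an optional manual-revision
round-trip through the ROI file) → lesion-mask algebra → tissue masks
(external labels or fallback clustering) → ADC and DSC perfusion maps →
region statistics CSV.  Every step is recorded in the provenance log with
parameter values and content hashes, and inputs are snapshot-copied before a
step may modify anything.

All statistics are computed in FLAIR space; quantitative maps are generated
on their native grid (shared with FLAIR for phantom data) and registered
when needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .diffusion import adc_axis_map, mean_adc_map
from .image import TimeSeriesImage, VolumeImage, load_series, load_volume
from .lesions import (NAWM_REF, Roi, RoiSet, class_masks, classify_lesions,
                      grow_lesion_roi, read_roiset, write_roiset)
from .perfusion import (DscSeries, aif_from_roi, detect_arrival, perfusion_maps,
                        select_aif, signal_to_concentration, volume_mean_series)
from .phantom import DEEP_STRUCTURES, PhantomBundle, TISSUE_CODES
from .report import ProvenanceLog, RegionStats, region_stats, write_csv
from .spatial import (AffineTransform, RigidOptions, apply_to_mask,
                      estimate_rigid, is_near_identity, resample)
from .tissues import TissueLabels, make_normal_appearing

__all__ = ["PipelineConfig", "PatientDataset", "PipelineResult", "run_pipeline"]

ALL_STEPS = ("coreg1", "lesions", "coreg2", "tissues", "maps", "coreg3", "analysis")


@dataclass
class PipelineConfig:
    """Tunable parameters of a pipeline run."""

    mf: float = 2.0                   # NAWM SD multiplier of Eq-style thresholds
    local_factor: float = 0.5         # lesion region-growing threshold fraction
    arrival_fraction: float = 0.1     # contrast-arrival detection fraction
    svd_threshold: float = 0.2        # SVD truncation (fraction of s_max)
    baseline_skip: int = 1            # discarded non-steady-state DSC volumes
    aif_n_voxels: int = 10
    vscale: float = 1.0               # skull-size volume scaling factor
    statistic: str = "mean"           # lesion summary statistic
    registration: str = "estimate"    # "estimate" or "identity"
    use_truth_tissues: bool = False   # phantom: use truth labels instead of fallback
    seed: int = 0
    revised_roi_file: str | None = None   # operator-edited ROI file to reload


@dataclass
class PatientDataset:
    """Everything one pipeline run consumes."""

    patient_id: str
    flair: VolumeImage
    t1: VolumeImage
    gd_t1: VolumeImage
    dwi_b0: VolumeImage
    dwi_x: VolumeImage
    dwi_y: VolumeImage
    dwi_z: VolumeImage
    dsc: TimeSeriesImage
    brain_mask: VolumeImage
    lesion_seeds: dict[int, tuple[int, int, int]]
    nawm_ref_voxels: list[tuple[int, int, int]]
    b_value: float = 1000.0
    tissue_labels: TissueLabels | None = None
    deep_labels: VolumeImage | None = None
    aif_roi: list[tuple[int, int, int]] | None = None

    @classmethod
    def from_bundle(cls, bundle: PhantomBundle, patient_id: str = "phantom",
                    use_truth_tissues: bool = False) -> "PatientDataset":
        tissue = None
        if use_truth_tissues:
            table = dict(TISSUE_CODES)
            table.update(DEEP_STRUCTURES)
            tissue = TissueLabels(bundle.truth_tissue_labels, code_table=table)
        return cls(
            patient_id=patient_id,
            flair=bundle.flair, t1=bundle.t1, gd_t1=bundle.gd_t1,
            dwi_b0=bundle.dwi_b0, dwi_x=bundle.dwi_x, dwi_y=bundle.dwi_y,
            dwi_z=bundle.dwi_z, dsc=bundle.dsc, brain_mask=bundle.brain_mask,
            lesion_seeds=bundle.lesion_seeds,
            nawm_ref_voxels=bundle.nawm_ref_voxels,
            b_value=bundle.spec.b_value,
            tissue_labels=tissue,
            deep_labels=bundle.truth_deep_labels,
        )

    @classmethod
    def from_dir(cls, path: str | Path, patient_id: str | None = None) -> "PatientDataset":
        """Load a normalized patient/phantom directory (canonical filenames
        plus a ``truth_manifest.json`` carrying seeds and acquisition info)."""
        path = Path(path)
        manifest = json.loads((path / "truth_manifest.json").read_text())

        def vol(name, space="flair"):
            for suffix in (".nii.gz", ".nii"):
                p = path / f"{name}{suffix}"
                if p.exists():
                    return load_volume(p, space=space)
            raise FileNotFoundError(f"missing sequence {name} in {path}")

        deep = None
        if (path / "truth_deep_labels.nii.gz").exists():
            deep = vol("truth_deep_labels")
        return cls(
            patient_id=patient_id or path.name,
            flair=vol("flair"), t1=vol("t1"), gd_t1=vol("gd_t1"),
            dwi_b0=vol("dwi_b0"), dwi_x=vol("dwi_x"), dwi_y=vol("dwi_y"),
            dwi_z=vol("dwi_z"),
            dsc=load_series(path / "dsc.nii.gz", tr_s=manifest["tr_s"],
                            te_s=manifest["te_s"]),
            brain_mask=vol("brain_mask"),
            lesion_seeds={int(k): tuple(v) for k, v in manifest["lesion_seeds"].items()},
            nawm_ref_voxels=_box_voxels(*manifest["nawm_ref_box"]),
            b_value=manifest.get("b_value", 1000.0),
            deep_labels=deep,
        )


def _box_voxels(corner, size):
    (x0, y0, z0), (dx, dy, dz) = corner, size
    return [(x, y, z) for x in range(x0, x0 + dx)
            for y in range(y0, y0 + dy) for z in range(z0, z0 + dz)]


@dataclass
class PipelineResult:
    patient_id: str
    rois: RoiSet | None = None
    transforms: dict[str, AffineTransform] = field(default_factory=dict)
    r_t1: VolumeImage | None = None
    r_gd_t1: VolumeImage | None = None
    masks: dict[str, VolumeImage] = field(default_factory=dict)
    nagm: VolumeImage | None = None
    nawm: VolumeImage | None = None
    tissue_labels: TissueLabels | None = None
    maps: dict = field(default_factory=dict)          # adc AdcResult, perfusion PerfusionResult
    stats_rows: list[RegionStats] = field(default_factory=list)
    csv_path: Path | None = None
    roi_file: Path | None = None
    paused_for_review: bool = False


def run_pipeline(data: PatientDataset, out_dir: str | Path,
                 config: PipelineConfig | None = None,
                 steps: tuple[str, ...] = ALL_STEPS,
                 pause_for_review: bool = False) -> PipelineResult:
    """Run the selected pipeline steps on one patient dataset.

    With ``pause_for_review=True`` the run stops after writing the
    classified ROI file so the operator can revise class codes; a later run
    with ``config.revised_roi_file`` set reloads the edited file and
    continues from the mask-building step.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = ProvenanceLog(out / "provenance")
    result = PipelineResult(patient_id=data.patient_id)

    # ---- coreg1: T1 and Gd-T1 into FLAIR space ---------------------------
    if "coreg1" in steps:
        vdir = log.begin_step("coreg1", {"registration": cfg.registration},
                              software_version=__version__)
        if cfg.registration == "identity":
            t_t1 = AffineTransform.identity("t1", "flair")
            t_gd = AffineTransform.identity("gd_t1", "flair")
            result.r_t1 = resample(data.t1, t_t1, data.flair, interp="linear") \
                if not data.t1.same_grid(data.flair) else data.flair.like(data.t1.data)
            result.r_gd_t1 = resample(data.gd_t1, t_gd, data.flair, interp="linear") \
                if not data.gd_t1.same_grid(data.flair) else data.flair.like(data.gd_t1.data)
        else:
            opts = RigidOptions()
            t_t1 = estimate_rigid(data.t1, data.flair, opts)
            t_gd = estimate_rigid(data.gd_t1, data.flair, opts)

            def _registered(img, transform):
                # sub-resolution transform on a shared grid: resampling would
                # only blur, so snap to identity
                if img.same_grid(data.flair) and is_near_identity(transform, data.flair):
                    return data.flair.like(img.data)
                return resample(img, transform, data.flair, interp="linear")

            result.r_t1 = _registered(data.t1, t_t1)
            result.r_gd_t1 = _registered(data.gd_t1, t_gd)
        result.transforms["t1_to_flair"] = t_t1
        result.transforms["gd_t1_to_flair"] = t_gd
        t_t1.save(vdir / "t1_to_flair.mat")
        t_gd.save(vdir / "gd_t1_to_flair.mat")
        log.finish_step("coreg1", outputs=[vdir / "t1_to_flair.mat",
                                           vdir / "gd_t1_to_flair.mat"])

    # ---- lesions: growing, NAWM reference, classification -----------------
    if "lesions" in steps:
        vdir = log.begin_step("lesions", {"mf": cfg.mf, "local_factor": cfg.local_factor,
                                          "statistic": cfg.statistic},
                              software_version=__version__)
        if cfg.revised_roi_file:
            rois = read_roiset(cfg.revised_roi_file)
        else:
            nawm_roi = Roi(id=0, voxels=list(data.nawm_ref_voxels),
                           class_code=NAWM_REF, label_text="NAWM reference")
            grown = [grow_lesion_roi(data.flair, seed, cfg.local_factor, roi_id=i)
                     for i, seed in sorted(data.lesion_seeds.items())]
            rois = RoiSet([nawm_roi] + grown)
            rois = classify_lesions(rois, result.r_t1, result.r_gd_t1,
                                    mf=cfg.mf, statistic=cfg.statistic)
        result.rois = rois
        result.roi_file = write_roiset(rois, vdir / "lesions.roi")
        log.finish_step("lesions", outputs=[result.roi_file])
        if pause_for_review:
            result.paused_for_review = True
            return result

    # ---- coreg2: lesion masks (transform reuse, no re-estimation) ---------
    if "coreg2" in steps and result.rois is not None:
        vdir = log.begin_step("coreg2", {}, software_version=__version__)
        result.masks = class_masks(result.rois, data.flair)
        # reuse the FLAIR<-T1 transform to carry the mask to native T1 space
        t_t1 = result.transforms.get("t1_to_flair",
                                     AffineTransform.identity("t1", "flair"))
        result.masks["total_on_t1"] = apply_to_mask(
            result.masks["total"], t_t1.inverse(), data.t1)
        saved = []
        for name in ("total", "C1", "C2", "C3", "C4"):
            saved.append(result.masks[name].save(vdir / f"lesion_{name}.nii.gz"))
        log.finish_step("coreg2", outputs=saved)

    # ---- tissues: NAGM/NAWM and deep structures ---------------------------
    if "tissues" in steps:
        vdir = log.begin_step("tissues", {"use_truth": cfg.use_truth_tissues,
                                          "seed": cfg.seed},
                              software_version=__version__)
        tissue = data.tissue_labels
        if tissue is None:
            from .tissues import fallback_tissue_segmentation
            tissue = fallback_tissue_segmentation(result.r_t1 or data.t1,
                                                  data.brain_mask, seed=cfg.seed)
        result.tissue_labels = tissue
        lesion_total = result.masks.get("total",
                                        data.flair.like(np.zeros(data.flair.shape, np.uint8)))
        result.nagm, result.nawm = make_normal_appearing(
            tissue.mask("gm"), tissue.mask("wm"), lesion_total)
        tissue.save(vdir / "tissue_labels.nii.gz")
        result.nagm.save(vdir / "nagm.nii.gz")
        result.nawm.save(vdir / "nawm.nii.gz")
        log.finish_step("tissues", outputs=[vdir / "nagm.nii.gz", vdir / "nawm.nii.gz"])

    # ---- maps: ADC and DSC perfusion --------------------------------------
    if "maps" in steps:
        vdir = log.begin_step("maps", {"b_value": data.b_value,
                                       "arrival_fraction": cfg.arrival_fraction,
                                       "svd_threshold": cfg.svd_threshold,
                                       "baseline_skip": cfg.baseline_skip},
                              software_version=__version__)
        per_axis = [adc_axis_map(data.dwi_b0, s_b, data.b_value, data.brain_mask)
                    for s_b in (data.dwi_x, data.dwi_y, data.dwi_z)]
        adc = mean_adc_map(*per_axis)
        result.maps["adc"] = adc

        dsc = DscSeries(data.dsc, data.brain_mask)
        mean_curve = volume_mean_series(dsc)
        arrival = detect_arrival(mean_curve, cfg.arrival_fraction)
        conc = signal_to_concentration(dsc, arrival, skip=cfg.baseline_skip)
        if data.aif_roi:
            aif = aif_from_roi(conc, data.aif_roi)
        else:
            aif = select_aif(conc, data.brain_mask, n_voxels=cfg.aif_n_voxels)
        perf = perfusion_maps(conc, aif, dsc.tr_s, data.brain_mask,
                              svd_threshold=cfg.svd_threshold, arrival_index=arrival)
        result.maps["perfusion"] = perf
        def save32(img, path):
            img.like(np.asarray(img.data, dtype=np.float32)).save(path)

        save32(adc.adc, vdir / "adc_mean.nii.gz")
        for i, name in enumerate(("adc_x", "adc_y", "adc_z")):
            save32(per_axis[i].adc, vdir / f"{name}.nii.gz")
        save32(perf.cbf, vdir / "cbf.nii.gz")
        save32(perf.cbv, vdir / "cbv.nii.gz")
        save32(perf.mtt, vdir / "mtt.nii.gz")
        (vdir / "aif.json").write_text(json.dumps(
            {"curve": [float(v) for v in aif.curve],
             "voxels": [list(v) for v in aif.voxels],
             "automatic": aif.automatic, "arrival_index": arrival}))
        log.finish_step("maps", outputs=[vdir / "adc_mean.nii.gz", vdir / "cbf.nii.gz",
                                         vdir / "cbv.nii.gz", vdir / "mtt.nii.gz",
                                         vdir / "aif.json"])

    # ---- analysis: region statistics CSV -----------------------------------
    if "analysis" in steps:
        vdir = log.begin_step("analysis", {"vscale": cfg.vscale},
                              software_version=__version__)
        result.stats_rows = _region_stats_rows(data, result, cfg)
        result.csv_path = write_csv(result.stats_rows, vdir / "region_stats.csv")
        log.finish_step("analysis", outputs=[result.csv_path])

    return result


def _region_masks(data: PatientDataset, result: PipelineResult) -> dict[str, VolumeImage]:
    regions: dict[str, VolumeImage] = {}
    if result.nagm is not None:
        regions["NAGM"] = result.nagm
        regions["NAWM"] = result.nawm
    if data.deep_labels is not None:
        deep = np.asarray(data.deep_labels.data)
        for name, code in DEEP_STRUCTURES.items():
            regions[f"basal_ganglia_{name}"] = data.deep_labels.like(
                (deep == code).astype(np.uint8))
    for name, mask in result.masks.items():
        if name == "total":
            regions["lesion_total"] = mask
        elif name in ("C1", "C2", "C3", "C4"):
            regions[f"lesion_{name}"] = mask
        elif name.startswith("lesion_") and not name.endswith("on_t1"):
            regions[name] = mask
    return regions


def _region_stats_rows(data: PatientDataset, result: PipelineResult,
                       cfg: PipelineConfig) -> list[RegionStats]:
    rows: list[RegionStats] = []
    adc = result.maps.get("adc")
    perf = result.maps.get("perfusion")
    maps: list[tuple[str, VolumeImage | None, VolumeImage | None]] = [("none", None, None)]
    if adc is not None:
        maps.append(("adc", adc.adc, adc.valid_mask))
    if perf is not None:
        cbf_valid = perf.cbf.like((np.asarray(perf.cbf.data) > 0).astype(np.uint8))
        maps += [("cbf", perf.cbf, cbf_valid), ("cbv", perf.cbv, None),
                 ("mtt", perf.mtt, cbf_valid)]
    for region, mask in _region_masks(data, result).items():
        for map_name, map_img, valid in maps:
            rows.append(region_stats(map_img, mask, data.patient_id, region,
                                     map_name, valid_mask=valid, vscale=cfg.vscale))
    return rows
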