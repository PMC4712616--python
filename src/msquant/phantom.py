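"""Digital multi-modal brain phantom with known ground truth.

The phantom emulates one patient's acquisition set — FLAIR, non-enhanced T1,
Gd-enhanced T1, DWI (b=0 plus three orthogonal b=1000 s/mm² channels) and a
4D DSC perfusion time series — over a simple geometric "brain": an ellipsoid
with a cortical grey-matter shell, central CSF ventricles, deep grey-matter
structures (caudate, putamen, globus pallidus, thalamus, left/right), a small
arterial region feeding the bolus, and spherical white-matter lesions of the
four evolution classes:

    C1  Gd-enhancing,     T1-isointense
    C2  Gd-enhancing,     T1-hypointense
    C3  non-enhancing,    T1-isointense
    C4  non-enhancing,    T1-hypointense ("black hole")

Forward models
--------------
* structural: tissue mean + lesion offset + N(0, noise_sd)
* diffusion:  S_b = S0 * exp(-b * ADC) per axis (isotropic truth)
* perfusion:  C_tissue(t) = CBF * (AIF ⊛ exp(-t/MTT)) computed as the
  continuous convolution integral (fine-grid quadrature, sampled at TR);
  signal S(t) = S0 * exp(-TE * C(t)).  Arterial voxels carry the AIF itself.

Every truth quantity (lesion labels and classes, tissue labels, ADC map,
CBF/CBV/MTT maps, contrast-arrival volume index) is returned alongside the
images, so each pipeline stage can be checked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import TimeSeriesImage, VolumeImage

__all__ = [
    "AifParams",
    "LesionSpec",
    "PhantomSpec",
    "PhantomBundle",
    "gamma_variate_aif",
    "generate_phantom",
    "default_lesion_specs",
    "write_bundle",
]

LESION_CLASSES = ("C1", "C2", "C3", "C4")

#: label codes of the truth tissue volume
TISSUE_CODES = {"background": 0, "csf": 1, "gm": 2, "wm": 3}

#: label codes of the deep grey-matter structure volume
DEEP_STRUCTURES = {
    "caudate_left": 10, "caudate_right": 11,
    "putamen_left": 12, "putamen_right": 13,
    "pallidum_left": 14, "pallidum_right": 15,
    "thalamus_left": 16, "thalamus_right": 17,
}


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate bolus parameters: C(t) = amp·(t−t0)^α·exp(−(t−t0)/β)."""

    t0_s: float = 9.5
    alpha: float = 1.0
    beta_s: float = 1.5
    amplitude: float = 4.0

    def validate(self) -> None:
        vals = (self.t0_s, self.alpha, self.beta_s, self.amplitude)
        if not all(np.isfinite(vals)):
            raise ValueError("aif_params: all parameters must be finite")
        if self.alpha <= 0 or self.beta_s <= 0 or self.amplitude <= 0:
            raise ValueError("aif_params: alpha, beta and amplitude must be > 0")

    @property
    def bolus_duration_s(self) -> float:
        # mode at alpha*beta; ~exhausted a few time constants later
        return self.alpha * self.beta_s + 5.0 * self.beta_s


@dataclass(frozen=True)
class LesionSpec:
    """One spherical lesion: where it sits, its true class, and how far its
    intensity departs from the surrounding white matter per modality."""

    center_vox: tuple[int, int, int]
    radius_mm: float
    true_class: str
    offsets: dict[str, float]  # modality -> additive intensity offset

    def validate(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"lesion_specs: radius must be > 0, got {self.radius_mm}")
        if self.true_class not in LESION_CLASSES:
            raise ValueError(f"lesion_specs: unknown class {self.true_class!r}")


def default_lesion_specs() -> list[LesionSpec]:
    """Eight white-matter lesions, two per class, inside the default grid.

    Offsets: +150 on FLAIR (hyperintense, segmentable), −40 on T1 for the
    hypointense classes (C2/C4), +40 on Gd-T1 for the enhancing classes
    (C1/C2).  Class-neutral modalities get offset 0.
    """
    t1_hypo, gd_enh = -40.0, 40.0
    defs = {
        "C1": {"flair": 150.0, "t1": 0.0, "gd_t1": gd_enh},
        "C2": {"flair": 150.0, "t1": t1_hypo, "gd_t1": gd_enh},
        "C3": {"flair": 150.0, "t1": 0.0, "gd_t1": 0.0},
        "C4": {"flair": 150.0, "t1": t1_hypo, "gd_t1": 0.0},
    }
    centers = [(14, 18, 12), (34, 18, 12), (14, 30, 12), (34, 30, 12),
               (18, 24, 8), (30, 24, 8), (18, 24, 16), (30, 24, 16)]
    classes = ["C1", "C1", "C2", "C2", "C3", "C3", "C4", "C4"]
    return [LesionSpec(c, 2.6, k, dict(defs[k])) for c, k in zip(centers, classes)]


@dataclass
class PhantomSpec:
    """Full parameterisation of the synthetic patient."""

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # modality -> tissue -> mean intensity
    tissue_means: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "flair": {"csf": 30.0, "gm": 120.0, "wm": 100.0},
        "t1": {"csf": 40.0, "gm": 80.0, "wm": 100.0},
        "gd_t1": {"csf": 40.0, "gm": 80.0, "wm": 100.0},
    })
    lesion_specs: list[LesionSpec] = field(default_factory=default_lesion_specs)
    nawm_ref_box: tuple[tuple[int, int, int], tuple[int, int, int]] = ((21, 12, 11), (6, 4, 3))
    # modality -> additive Gaussian noise SD
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "flair": 0.0, "t1": 0.0, "gd_t1": 0.0, "dwi": 0.0, "dsc": 0.0,
    })
    adc_truth: dict[str, float] = field(default_factory=lambda: {
        "csf": 3.0e-3, "gm": 0.9e-3, "wm": 0.7e-3, "lesion": 1.0e-3,
    })
    # tissue -> (CBF_rel 1/s, CBV_rel, MTT s); MTT = CBV/CBF must hold
    perf_truth: dict[str, tuple[float, float, float]] = field(default_factory=lambda: {
        "csf": (0.001, 0.004, 4.0),
        "gm": (0.02, 0.08, 4.0),
        "wm": (0.01, 0.04, 4.0),
        "lesion": (0.008, 0.032, 4.0),
    })
    aif_params: AifParams = field(default_factory=AifParams)
    n_timepoints: int = 60
    tr_s: float = 1.0
    te_s: float = 0.03
    b_value: float = 1000.0
    dwi_s0: dict[str, float] = field(default_factory=lambda: {
        "csf": 1200.0, "gm": 1000.0, "wm": 900.0, "lesion": 950.0,
    })
    dsc_s0: float = 100.0
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_mm
        return aff

    def validate(self) -> None:
        if any(s < 2 for s in self.grid_shape):
            raise ValueError("grid_shape: each axis needs >= 2 voxels")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm: voxel sizes must be > 0")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{name!r}]: must be >= 0")
        for tissue, (cbf, cbv, mtt) in self.perf_truth.items():
            if cbf <= 0 or cbv <= 0 or mtt <= 0:
                raise ValueError(f"perf_truth[{tissue!r}]: values must be > 0")
            if abs(mtt - cbv / cbf) > 1e-9 * mtt:
                raise ValueError(
                    f"perf_truth[{tissue!r}]: MTT must equal CBV/CBF "
                    f"(got {mtt}, expected {cbv / cbf})")
        self.aif_params.validate()
        horizon = self.n_timepoints * self.tr_s
        if horizon <= self.aif_params.t0_s + self.aif_params.bolus_duration_s:
            raise ValueError("n_timepoints: acquisition must outlast t0 + bolus duration")
        if self.b_value <= 0:
            raise ValueError("b_value: must be > 0")
        # lesion geometry: inside grid, pairwise disjoint
        masks = []
        for les in self.lesion_specs:
            les.validate()
            m = _sphere_mask(self.grid_shape, self.voxel_mm, les.center_vox, les.radius_mm)
            if not m.any():
                raise ValueError("lesion_specs: lesion sphere contains no voxel")
            r_vox = np.array(les.radius_mm) / np.array(self.voxel_mm)
            lo = np.array(les.center_vox) - r_vox
            hi = np.array(les.center_vox) + r_vox
            if np.any(lo < 0) or np.any(hi > np.array(self.grid_shape) - 1):
                raise ValueError(f"lesion_specs: lesion at {les.center_vox} leaves the grid")
            for prev in masks:
                if (m & prev).any():
                    raise ValueError(f"lesion_specs: lesion at {les.center_vox} overlaps another lesion")
            masks.append(m)


@dataclass
class PhantomBundle:
    """Generated images plus every ground-truth quantity."""

    flair: VolumeImage
    t1: VolumeImage
    gd_t1: VolumeImage
    dwi_b0: VolumeImage
    dwi_x: VolumeImage
    dwi_y: VolumeImage
    dwi_z: VolumeImage
    dsc: TimeSeriesImage
    brain_mask: VolumeImage
    truth_lesion_labels: VolumeImage       # 0 background, 1..n per lesion
    truth_classes: dict[int, str]          # lesion id -> C1..C4
    truth_tissue_labels: VolumeImage       # TISSUE_CODES
    truth_deep_labels: VolumeImage         # DEEP_STRUCTURES codes
    truth_artery: VolumeImage              # binary AIF region
    truth_adc: VolumeImage                 # mm^2/s
    truth_cbf: VolumeImage
    truth_cbv: VolumeImage
    truth_mtt: VolumeImage
    truth_arrival: int
    spec: PhantomSpec

    @property
    def lesion_seeds(self) -> dict[int, tuple[int, int, int]]:
        """Lesion id -> center voxel; emulates the operator's seed clicks."""
        return {i + 1: les.center_vox for i, les in enumerate(self.spec.lesion_specs)}

    @property
    def nawm_ref_voxels(self) -> list[tuple[int, int, int]]:
        (x0, y0, z0), (dx, dy, dz) = self.spec.nawm_ref_box
        return [(x, y, z)
                for x in range(x0, x0 + dx)
                for y in range(y0, y0 + dy)
                for z in range(z0, z0 + dz)]


def gamma_variate_aif(params: AifParams, times: np.ndarray) -> np.ndarray:
    """Gamma-variate bolus curve C(t) = amp·(t−t0)^α·exp(−(t−t0)/β), 0 for t ≤ t0.

    ``times`` must be nondecreasing and start at 0 (seconds).
    """
    params.validate()
    t = np.asarray(times, dtype=float)
    if t.size and (t[0] != 0 or np.any(np.diff(t) < 0)):
        raise ValueError("times must be nondecreasing and start at 0")
    dt = t - params.t0_s
    curve = np.zeros_like(t)
    pos = dt > 0
    curve[pos] = params.amplitude * dt[pos] ** params.alpha * np.exp(-dt[pos] / params.beta_s)
    return curve


def toeplitz_convolve(aif: np.ndarray, residue: np.ndarray, tr_s: float) -> np.ndarray:
    """Discrete tissue curve C[i] = tr·Σ_{j≤i} aif[j]·residue[i−j].

    The rectangular quadrature matching the SVD deconvolution stage's
    Toeplitz system; used by the deconvolution oracle tests.
    """
    n = len(aif)
    full = np.convolve(aif, residue)[:n]
    return tr_s * full


def continuous_tissue_curve(params: AifParams, cbf_rel: float, mtt_s: float,
                            times: np.ndarray, tr_s: float,
                            supersample: int = 20) -> np.ndarray:
    """Tissue concentration CBF·(AIF ⊛ e^{−t/MTT}) evaluated at the samples.

    The convolution integral is computed on a grid ``supersample`` times
    finer than TR and then sampled at the acquisition times, so the phantom
    carries the *continuous* indicator-dilution truth: MTT is the exact
    exponential time constant and CBV = CBF·MTT holds as an integral
    identity, independent of the deconvolution stage's discretisation.
    """
    dt = tr_s / supersample
    t_fine = np.arange(0.0, times[-1] + tr_s, dt)
    aif_fine = gamma_variate_aif(params, t_fine)
    residue_fine = np.exp(-t_fine / mtt_s)
    conv = dt * np.convolve(aif_fine, cbf_rel * residue_fine)[:len(t_fine)]
    return conv[::supersample][:len(times)]


def _sphere_mask(shape, voxel_mm, center_vox, radius_mm) -> np.ndarray:
    grids = np.ogrid[:shape[0], :shape[1], :shape[2]]
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center_vox, voxel_mm))
    return d2 <= radius_mm ** 2


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[:shape[0], :shape[1], :shape[2]]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d2 <= 1.0


def _build_geometry(spec: PhantomSpec):
    """Tissue labels, deep-structure labels, artery mask, lesion labels."""
    shape = spec.grid_shape
    center = tuple((s - 1) / 2 for s in shape)
    # anisotropic in-plane (narrower left-right than anterior-posterior),
    # as real heads are; also makes in-plane rotation identifiable
    semi = (0.36 * shape[0], 0.44 * shape[1], 0.42 * shape[2])
    brain = _ellipsoid_mask(shape, center, semi)
    inner = _ellipsoid_mask(shape, center, tuple(0.8 * a for a in semi))

    tissue = np.zeros(shape, dtype=np.int16)
    tissue[brain] = TISSUE_CODES["gm"]       # cortical shell
    tissue[inner] = TISSUE_CODES["wm"]
    vent = _ellipsoid_mask(shape, center, tuple(max(1.5, 0.14 * s) for s in shape))
    vent &= inner
    tissue[vent] = TISSUE_CODES["csf"]

    deep = np.zeros(shape, dtype=np.int16)
    cx, cy, cz = center
    sx = 0.16 * shape[0]
    offsets = {
        "caudate": (0.0, 0.28 * shape[1] * 0.35, 0.0),
        "putamen": (0.35 * sx, 0.0, 0.0),
        "pallidum": (0.0, -0.28 * shape[1] * 0.2, 0.0),
        "thalamus": (0.0, -0.28 * shape[1] * 0.45, 0.0),
    }
    for name, (dx, dy, dz) in offsets.items():
        for side, sign in (("left", -1), ("right", 1)):
            c = (cx + sign * (sx + dx), cy + dy, cz + dz)
            m = _sphere_mask(shape, spec.voxel_mm,
                             tuple(int(round(v)) for v in c), 1.6 * spec.voxel_mm[0])
            m &= tissue == TISSUE_CODES["wm"]
            deep[m] = DEEP_STRUCTURES[f"{name}_{side}"]
    # deep structures are grey matter: the tissue truth says so too
    tissue[deep > 0] = TISSUE_CODES["gm"]

    # arterial region: small sphere near the inferior brain edge, inside brain
    art_center = (int(cx), int(round(cy - 0.36 * shape[1])), int(cz))
    artery = _sphere_mask(shape, spec.voxel_mm, art_center, 1.9 * spec.voxel_mm[0]) & brain

    lesion_labels = np.zeros(shape, dtype=np.int16)
    for i, les in enumerate(spec.lesion_specs, start=1):
        m = _sphere_mask(shape, spec.voxel_mm, les.center_vox, les.radius_mm)
        lesion_labels[m] = i
    return brain, tissue, deep, artery, lesion_labels


def _tissue_value_map(tissue: np.ndarray, deep: np.ndarray,
                      values: dict[str, float], deep_as: str = "gm") -> np.ndarray:
    out = np.zeros(tissue.shape, dtype=float)
    for name in ("csf", "gm", "wm"):
        out[tissue == TISSUE_CODES[name]] = values[name]
    if deep_as in values:
        out[deep > 0] = values[deep_as]
    return out


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Build the full synthetic patient; same spec + seed → identical bundle."""
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine
    brain, tissue, deep, artery, lesion_labels = _build_geometry(spec)
    lesion_any = lesion_labels > 0

    def vol(data, space):
        return VolumeImage(data, affine, space=space)

    # --- structural modalities -------------------------------------------
    structural = {}
    for modality in ("flair", "t1", "gd_t1"):
        img = _tissue_value_map(tissue, deep, spec.tissue_means[modality])
        for i, les in enumerate(spec.lesion_specs, start=1):
            m = lesion_labels == i
            base = spec.tissue_means[modality]["wm"]
            img[m] = base + les.offsets.get(modality, 0.0)
        sd = spec.noise_sd.get(modality, 0.0)
        if sd > 0:
            img = img + rng.normal(0.0, sd, img.shape)
        structural[modality] = vol(img, "flair")

    # --- diffusion --------------------------------------------------------
    adc = _tissue_value_map(tissue, deep, spec.adc_truth)
    adc[lesion_any] = spec.adc_truth["lesion"]
    s0 = _tissue_value_map(tissue, deep, spec.dwi_s0)
    s0[lesion_any] = spec.dwi_s0["lesion"]
    attenuated = s0 * np.exp(-spec.b_value * adc)
    dwi_sd = spec.noise_sd.get("dwi", 0.0)
    dwi_vols = {}
    for name, base in (("dwi_b0", s0), ("dwi_x", attenuated),
                       ("dwi_y", attenuated), ("dwi_z", attenuated)):
        data = base.copy()
        if dwi_sd > 0:
            data = data + rng.normal(0.0, dwi_sd, data.shape)
        dwi_vols[name] = vol(data, "flair")

    # --- perfusion --------------------------------------------------------
    times = np.arange(spec.n_timepoints) * spec.tr_s
    aif = gamma_variate_aif(spec.aif_params, times)
    truth_arrival = int(np.argmax(times > spec.aif_params.t0_s))

    cbf = np.zeros(spec.grid_shape)
    cbv = np.zeros(spec.grid_shape)
    mtt = np.zeros(spec.grid_shape)
    conc = np.zeros(spec.grid_shape + (spec.n_timepoints,))
    curves: dict[str, np.ndarray] = {}
    for name in ("csf", "gm", "wm", "lesion"):
        f, v, m = spec.perf_truth[name]
        curves[name] = continuous_tissue_curve(spec.aif_params, f, m, times, spec.tr_s)
    for name in ("csf", "gm", "wm"):
        sel = (tissue == TISSUE_CODES[name]) & ~lesion_any & ~artery
        f, v, m = spec.perf_truth[name]
        cbf[sel], cbv[sel], mtt[sel] = f, v, m
        conc[sel] = curves[name]
    sel = lesion_any & ~artery
    f, v, m = spec.perf_truth["lesion"]
    cbf[sel], cbv[sel], mtt[sel] = f, v, m
    conc[sel] = curves["lesion"]
    conc[artery] = aif

    dsc_data = spec.dsc_s0 * np.exp(-spec.te_s * conc)
    dsc_data[~brain] = 0.0
    dsc_sd = spec.noise_sd.get("dsc", 0.0)
    if dsc_sd > 0:
        dsc_data = dsc_data + rng.normal(0.0, dsc_sd, dsc_data.shape)

    return PhantomBundle(
        flair=structural["flair"], t1=structural["t1"], gd_t1=structural["gd_t1"],
        dwi_b0=dwi_vols["dwi_b0"], dwi_x=dwi_vols["dwi_x"],
        dwi_y=dwi_vols["dwi_y"], dwi_z=dwi_vols["dwi_z"],
        dsc=TimeSeriesImage(dsc_data, affine, tr_s=spec.tr_s, te_s=spec.te_s),
        brain_mask=vol(brain.astype(np.uint8), "flair"),
        truth_lesion_labels=vol(lesion_labels, "flair"),
        truth_classes={i + 1: les.true_class for i, les in enumerate(spec.lesion_specs)},
        truth_tissue_labels=vol(tissue, "flair"),
        truth_deep_labels=vol(deep, "flair"),
        truth_artery=vol(artery.astype(np.uint8), "flair"),
        truth_adc=vol(adc, "flair"),
        truth_cbf=vol(cbf, "flair"), truth_cbv=vol(cbv, "flair"), truth_mtt=vol(mtt, "flair"),
        truth_arrival=truth_arrival,
        spec=spec,
    )


def write_bundle(bundle: PhantomBundle, out_dir: str | Path) -> Path:
    """Write the bundle as NIfTI files plus a JSON truth manifest.

    Filenames mirror the pipeline's canonical sequence names so a phantom
    directory is indistinguishable from a normalised patient directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = ["flair", "t1", "gd_t1", "dwi_b0", "dwi_x", "dwi_y", "dwi_z"]
    for name in names:
        getattr(bundle, name).save(out / f"{name}.nii.gz")
    bundle.dsc.save(out / "dsc.nii.gz")
    bundle.brain_mask.save(out / "brain_mask.nii.gz")
    for name in ("truth_lesion_labels", "truth_tissue_labels", "truth_deep_labels",
                 "truth_artery", "truth_adc", "truth_cbf", "truth_cbv", "truth_mtt"):
        getattr(bundle, name).save(out / f"{name}.nii.gz")
    manifest = {
        "truth_arrival": bundle.truth_arrival,
        "truth_classes": {str(k): v for k, v in bundle.truth_classes.items()},
        "lesion_seeds": {str(k): list(v) for k, v in bundle.lesion_seeds.items()},
        "nawm_ref_box": [list(bundle.spec.nawm_ref_box[0]), list(bundle.spec.nawm_ref_box[1])],
        "tr_s": bundle.spec.tr_s, "te_s": bundle.spec.te_s,
        "b_value": bundle.spec.b_value,
        "deep_structure_codes": DEEP_STRUCTURES,
        "tissue_codes": TISSUE_CODES,
    }
    (out / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
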