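"""DSC-MRI perfusion quantification.

A dynamic susceptibility contrast (DSC) acquisition monitors the T2* signal
drop as a paramagnetic bolus transits the brain.  The processing chain is:

1. *Arrival detection* — the contrast-arrival volume is found on the
   brain-mean intensity curve: the detector flags the first volume whose
   absolute difference from the running mean of all previous volumes exceeds
   an adjustable threshold, expressed as a fraction of the curve's global
   max−min range (so it is insensitive to the absolute intensity level).
2. *Concentration* — per voxel, C(t) = −ln(S(t)/S0)/TE with S0 the
   pre-arrival baseline mean (the first ``skip`` non-steady-state volumes
   discarded).
3. *AIF selection* — arterial-input-function voxels are ranked by a score
   combining high peak concentration, early time-to-peak and narrow bolus
   width (FWHM); the AIF is the mean curve of the top candidates, which are
   reported for visual verification.  A user-supplied ROI overrides this.
4. *Deconvolution* — the tissue curve C = A·k is inverted by truncated SVD,
   where A is the lower-triangular Toeplitz quadrature of the AIF
   (A[i,j] = TR·AIF[i−j]) and k(t) = CBF·R(t) the flow-scaled residue.

Maps (all relative units — no hematocrit/density constants):
    CBF = max_t k(t);  CBV = ∫C dt / ∫AIF dt (trapezoidal);  MTT = CBV/CBF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .image import TimeSeriesImage, VolumeImage

__all__ = [
    "DscSeries", "PerfusionResult", "AifSelection", "ArrivalNotFound",
    "volume_mean_series", "detect_arrival", "signal_to_concentration",
    "select_aif", "aif_from_roi", "svd_deconvolve", "perfusion_maps",
]


class ArrivalNotFound(RuntimeError):
    """No volume-to-baseline jump exceeded the detection threshold."""


@dataclass
class DscSeries:
    """A 4D DSC acquisition plus its brain mask."""

    series: TimeSeriesImage
    brain_mask: VolumeImage

    def __post_init__(self) -> None:
        if self.series.n_timepoints < 8:
            raise ValueError("DSC series needs >= 8 timepoints")
        if self.series.data.shape[:3] != self.brain_mask.shape:
            raise ValueError("brain mask must match the DSC grid")

    @property
    def tr_s(self) -> float:
        return self.series.tr_s

    @property
    def te_s(self) -> float:
        return self.series.te_s


@dataclass
class AifSelection:
    """The arterial input function and where it came from."""

    curve: np.ndarray
    voxels: list[tuple[int, int, int]]
    automatic: bool = True


@dataclass
class PerfusionResult:
    cbf: VolumeImage            # relative flow (ml/100g/min-scale units)
    cbv: VolumeImage            # relative volume (ml/100g-scale units)
    mtt: VolumeImage            # seconds
    aif: AifSelection
    arrival_index: int
    svd_threshold: float
    units_relative: bool = True


def volume_mean_series(dsc: DscSeries) -> np.ndarray:
    """Mean intensity over the brain mask, one value per volume."""
    mask = np.asarray(dsc.brain_mask.data, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    return np.asarray(dsc.series.data, dtype=float)[mask].mean(axis=0)


def detect_arrival(series: np.ndarray, fraction: float = 0.1) -> int:
    """Contrast-arrival volume index on a per-volume mean curve.

    Threshold T = fraction·(max−min) of the whole curve.  The baseline at
    step k is the cumulative mean of volumes 0..k−1 (noise averaging);
    arrival is the smallest k with |series[k] − baseline_k| > T.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise ValueError("series needs >= 4 volumes")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = series.max() - series.min()
    if rng == 0:
        raise ArrivalNotFound("flat mean-intensity curve: no contrast arrival")
    threshold = fraction * rng
    baseline = np.cumsum(series)[:-1] / np.arange(1, series.size)
    jumps = np.abs(series[1:] - baseline) > threshold
    if not jumps.any():
        raise ArrivalNotFound(f"no volume-to-baseline jump exceeded {threshold:.4g}")
    return int(np.argmax(jumps)) + 1


def signal_to_concentration(dsc: DscSeries, arrival_index: int,
                            skip: int = 1) -> np.ndarray:
    """Per-voxel contrast concentration C(t) = −ln(S(t)/S0)/TE.

    S0 is the mean of the baseline volumes ``skip .. arrival_index−1`` (the
    first ``skip`` volumes are discarded as non-steady-state).  Voxels or
    timepoints without positive signal get C = 0.
    """
    if arrival_index < 2:
        raise ValueError("arrival_index must be >= 2 to leave baseline volumes")
    if not 0 <= skip < arrival_index:
        raise ValueError("skip must satisfy 0 <= skip < arrival_index")
    data = np.asarray(dsc.series.data, dtype=float)
    s0 = data[..., skip:arrival_index].mean(axis=-1)
    conc = np.zeros_like(data)
    ok = (data > 0) & (s0 > 0)[..., None]
    ratio = np.divide(data, s0[..., None], out=np.ones_like(data), where=ok)
    conc[ok] = (-np.log(ratio) / dsc.te_s)[ok]
    return conc


def _percentile_ranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(values.size)
    return ranks / max(values.size - 1, 1)


def select_aif(conc: np.ndarray, brain_mask: VolumeImage,
               n_voxels: int = 10) -> AifSelection:
    """Automatic AIF-like voxel detection.

    Candidates are brain voxels with a positive concentration peak, scored
    by percentile rank of (high peak) + (early time-to-peak) + (narrow
    FWHM); the AIF is the voxelwise mean curve of the ``n_voxels`` best.
    """
    if not np.all(np.isfinite(conc)):
        raise ValueError("concentration volume contains non-finite values")
    mask = np.asarray(brain_mask.data, dtype=bool)
    coords = np.argwhere(mask)
    curves = conc[mask]                      # (n_vox, T)
    peaks = curves.max(axis=1)
    usable = peaks > 0
    if not usable.any():
        raise ValueError("no brain voxel with positive concentration peak")
    coords, curves, peaks = coords[usable], curves[usable], peaks[usable]
    ttp = curves.argmax(axis=1).astype(float)
    fwhm = (curves >= 0.5 * peaks[:, None]).sum(axis=1).astype(float)
    score = (_percentile_ranks(peaks)
             + _percentile_ranks(-ttp)
             + _percentile_ranks(-fwhm))
    best = np.argsort(score, kind="stable")[::-1][:n_voxels]
    return AifSelection(
        curve=curves[best].mean(axis=0),
        voxels=[tuple(int(i) for i in coords[b]) for b in best],
        automatic=True,
    )


def aif_from_roi(conc: np.ndarray,
                 voxels: list[tuple[int, int, int]]) -> AifSelection:
    """Manual-override AIF: mean concentration curve over an operator ROI."""
    if not voxels:
        raise ValueError("AIF ROI is empty")
    curve = np.mean([conc[v] for v in voxels], axis=0)
    return AifSelection(curve=curve, voxels=list(voxels), automatic=False)


def _truncated_pinv(aif: np.ndarray, tr_s: float, svd_threshold: float):
    n = len(aif)
    a = tr_s * toeplitz(np.asarray(aif, dtype=float), np.zeros(n))
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    # numerically-zero singular values are always dropped (the AIF Toeplitz
    # matrix is rank-deficient when the bolus starts with zeros), so a zero
    # threshold means the plain pseudoinverse
    cutoff = max(svd_threshold, 1e-12) * s[0]
    keep = s >= cutoff
    if not keep.any():
        raise ValueError("all singular values fall below the truncation cutoff")
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return vt.T * s_inv, u.T


def svd_deconvolve(c_tissue: np.ndarray, aif: np.ndarray, tr_s: float,
                   svd_threshold: float = 0.2) -> np.ndarray:
    """Recover the flow-scaled residue k(t) = CBF·R(t) by truncated SVD.

    Solves C = A·k with A[i,j] = TR·AIF[i−j] (j ≤ i); singular values below
    ``svd_threshold``·s_max are zeroed before inversion.
    """
    c_tissue = np.asarray(c_tissue, dtype=float)
    aif = np.asarray(aif, dtype=float)
    if c_tissue.shape != aif.shape or c_tissue.size < 8:
        raise ValueError("curves must share a length >= 8")
    if not np.any(aif):
        raise ValueError("AIF must not be all-zero")
    v_sinv, ut = _truncated_pinv(aif, tr_s, svd_threshold)
    return v_sinv @ (ut @ c_tissue)


def perfusion_maps(conc: np.ndarray, aif: AifSelection, tr_s: float,
                   brain_mask: VolumeImage, svd_threshold: float = 0.2,
                   arrival_index: int = 0, cbf_eps: float = 1e-12) -> PerfusionResult:
    """CBF/CBV/MTT maps for every masked voxel.

    CBF = max_t k(t) from the SVD deconvolution; CBV is the trapezoidal
    integral ratio ∫C_tissue/∫AIF; MTT = CBV/CBF where CBF > ``cbf_eps``
    (the central volume theorem), 0 elsewhere.  Negative estimates are
    clamped to 0 so all maps stay nonnegative.
    """
    aif_integral = float(np.trapezoid(aif.curve, dx=tr_s))
    if aif_integral <= 0:
        raise ValueError("AIF integral must be positive")
    mask = np.asarray(brain_mask.data, dtype=bool)
    curves = conc[mask].T                                   # (T, n_vox)
    v_sinv, ut = _truncated_pinv(aif.curve, tr_s, svd_threshold)
    k = v_sinv @ (ut @ curves)
    cbf_vals = np.maximum(k.max(axis=0), 0.0)
    cbv_vals = np.maximum(np.trapezoid(curves, dx=tr_s, axis=0) / aif_integral, 0.0)
    mtt_vals = np.where(cbf_vals > cbf_eps, cbv_vals / np.where(cbf_vals > cbf_eps, cbf_vals, 1.0), 0.0)

    def to_vol(vals):
        out = np.zeros(mask.shape)
        out[mask] = vals
        return brain_mask.like(out)

    return PerfusionResult(
        cbf=to_vol(cbf_vals), cbv=to_vol(cbv_vals), mtt=to_vol(mtt_vals),
        aif=aif, arrival_index=arrival_index, svd_threshold=svd_threshold,
    )
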