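"""Apparent diffusion coefficient (ADC) maps from b=0 / b=1000 pairs.

With the Stejskal–Tanner two-point scheme the signal at diffusion weighting
b relates to the unweighted signal by S_b = S0·exp(−b·ADC), so per voxel

    ADC = ln(S0 / S_b) / b        [mm²/s]

One ADC map is computed per diffusion-gradient axis (x, y, z at
b = 1000 s/mm²) and the isotropic map is their voxelwise arithmetic mean.
Voxels failing positivity (S0 ≤ 0, S_b ≤ 0, or S_b > S0 giving a negative
coefficient) are set to 0 and counted; downstream region statistics exclude
them via the validity mask rather than treating the zeros as measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import VolumeImage

__all__ = ["AdcResult", "adc_axis_map", "mean_adc_map"]


@dataclass
class AdcResult:
    """An ADC map plus its validity bookkeeping."""

    adc: VolumeImage          # mm^2/s, 0 where invalid
    valid_mask: VolumeImage   # 1 where the coefficient is a real measurement
    n_clamped: int            # negative ADC voxels clamped to 0
    n_nonpositive: int        # voxels with nonpositive signal in the mask


def adc_axis_map(s0: VolumeImage, s_b: VolumeImage, b_value: float,
                 brain_mask: VolumeImage | None = None) -> AdcResult:
    """Single-axis ADC map: ln(s0/s_b)/b inside the brain mask."""
    if b_value <= 0:
        raise ValueError("b_value must be > 0")
    if not s0.same_grid(s_b):
        raise ValueError("s0 and s_b must share a grid")
    mask = np.ones(s0.shape, dtype=bool) if brain_mask is None \
        else np.asarray(brain_mask.data, dtype=bool)
    a = np.asarray(s0.data, dtype=float)
    b = np.asarray(s_b.data, dtype=float)
    positive = (a > 0) & (b > 0) & mask
    adc = np.zeros(s0.shape)
    adc[positive] = np.log(a[positive] / b[positive]) / b_value
    negative = adc < 0
    n_clamped = int(np.count_nonzero(negative))
    adc[negative] = 0.0
    valid = positive & ~negative
    return AdcResult(
        adc=s0.like(adc),
        valid_mask=s0.like(valid.astype(np.uint8)),
        n_clamped=n_clamped,
        n_nonpositive=int(np.count_nonzero(mask & ~positive)),
    )


def mean_adc_map(adc_x: AdcResult, adc_y: AdcResult, adc_z: AdcResult) -> AdcResult:
    """Isotropic ADC: voxelwise mean of the three per-axis maps.

    A voxel of the mean map is valid only where all three axis maps are.
    """
    maps = (adc_x, adc_y, adc_z)
    for m in maps[1:]:
        if not maps[0].adc.same_grid(m.adc):
            raise ValueError("per-axis ADC maps must share a grid")
    mean = np.mean([np.asarray(m.adc.data, dtype=float) for m in maps], axis=0)
    valid = np.logical_and.reduce([np.asarray(m.valid_mask.data, dtype=bool) for m in maps])
    mean = np.where(valid, mean, 0.0)
    return AdcResult(
        adc=maps[0].adc.like(mean),
        valid_mask=maps[0].adc.like(valid.astype(np.uint8)),
        n_clamped=sum(m.n_clamped for m in maps),
        n_nonpositive=sum(m.n_nonpositive for m in maps),
    )
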