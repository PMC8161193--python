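"""Voxelwise parameter maps: ADC, computed high-b DWI, and relative %FF.

With exactly two b-values the least-squares mono-exponential fit reduces to
the closed form ``ADC = ln(S_low / S_high) / (b_high - b_low)``; this module
uses that form directly. Invalid voxels (non-positive DW signal, or
fat + water below epsilon) are carried as NaN in the map data; downstream
refinement treats NaN as excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import UM2_PER_MM2
from .geometry import ImageVolume, require_same_grid

log = logging.getLogger(__name__)


@dataclass
class ParamMaps:
    """ADC (um^2/s) and %FF maps on the DWI grid, plus their joint validity."""
    adc: ImageVolume
    ff: ImageVolume

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.adc.data) & np.isfinite(self.ff.data)


def compute_adc(s_low: ImageVolume, s_high: ImageVolume,
                b_low: float, b_high: float) -> ImageVolume:
    """ADC map in um^2/s from a two-b-value DW pair.

    Voxels where either signal is <= 0 are NaN (log undefined). Negative ADC
    (signal increasing with b, i.e. noise) is retained as computed; callers
    can count it via ``negative_adc_fraction``.
    """
    require_same_grid(s_low, s_high, "ADC computation")
    if b_high <= b_low or b_low < 0:
        raise ValueError(f"need b_high > b_low >= 0, got {b_low}, {b_high}")
    lo = np.asarray(s_low.data, dtype=np.float64)
    hi = np.asarray(s_high.data, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(lo / hi) / (b_high - b_low) * UM2_PER_MM2
    adc[(lo <= 0) | (hi <= 0)] = np.nan
    n_bad = int(np.sum(~np.isfinite(adc)))
    if n_bad:
        log.debug("ADC: %d invalid voxels (non-positive signal)", n_bad)
    return ImageVolume(adc, s_low.geometry, "adc")


def negative_adc_fraction(adc: ImageVolume) -> float:
    ok = np.isfinite(adc.data)
    return float(np.mean(adc.data[ok] < 0)) if ok.any() else 0.0


def compute_cdwi(s_high: ImageVolume, adc: ImageVolume,
                 b_high: float, b_target: float) -> ImageVolume:
    """Computed (simulated) high-b image: mono-exponential extrapolation of
    the measured b_high signal to a virtual b_target.

    Invalid-ADC voxels map to 0. Negative fitted ADC is clamped to 0 for the
    extrapolation so the synthetic image never amplifies signal (noise-only
    voxels would otherwise blow up exponentially).
    """
    require_same_grid(s_high, adc, "cDWI computation")
    if b_target < b_high:
        raise ValueError(f"b_target ({b_target}) must be >= b_high ({b_high})")
    a = np.clip(adc.data, 0.0, None) / UM2_PER_MM2    # mm^2/s
    out = s_high.data * np.exp(-(b_target - b_high) * a)
    out = np.where(np.isfinite(adc.data), out, 0.0)
    return ImageVolume(out, s_high.geometry, "cdwi")


def compute_ff(fat: ImageVolume, water: ImageVolume,
               epsilon: float = 1e-9) -> ImageVolume:
    """Relative fat fraction map: FF = Fat / (Water + Fat) * 100.

    Negative inputs are clipped to 0 (count logged); voxels whose total
    signal is <= epsilon are NaN (ratio undefined).
    """
    require_same_grid(fat, water, "%FF computation")
    f = np.asarray(fat.data, dtype=np.float64)
    w = np.asarray(water.data, dtype=np.float64)
    n_neg = int(np.sum(f < 0) + np.sum(w < 0))
    if n_neg:
        log.info("%%FF: clipped %d negative input voxels to 0", n_neg)
    f = np.clip(f, 0.0, None)
    w = np.clip(w, 0.0, None)
    total = f + w
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(total > epsilon, f / total * 100.0, np.nan)
    return ImageVolume(ff, fat.geometry, "ff")
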