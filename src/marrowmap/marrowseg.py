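"""Bone-marrow segmentation on the computed high-b image, refinement, and QC.

Marrow appears hyperintense on high-b DWI relative to surrounding tissue, so
an intensity threshold on the computed high-b stack yields a candidate mask.
The operator-interactive thresholding of the emulated workflow is replaced by
Otsu's method on the nonzero-intensity histogram (reproducible), with a
manual threshold preserved as an option. The mask is then refined by the
physiologic rules: exclude voxels with ADC > 1000 um^2/s or %FF < 15%
(residual soft tissue / noise); invalid (NaN) map voxels cannot satisfy the
inequalities and are excluded too.

Subjects whose marrow is hypointense on DWI (e.g. high marrow fat content)
defeat threshold segmentation; the QC report flags them via a minimum marrow
voxel count and a minimum marrow-to-muscle b900 signal ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import GridGeometry, ImageVolume, require_same_grid

log = logging.getLogger(__name__)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on a 1-D sample: the cut over ``nbins`` histogram
    bins that maximizes between-class variance.

    Returns the *upper edge* of the last background bin, so that
    ``values > threshold`` excludes the entire background class even when a
    piecewise-constant image concentrates a whole tissue class in the
    boundary bin (bin-center conventions misclassify that case).
    """
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(np.float64) / hist.sum()
    omega0 = np.cumsum(w)
    mu_cum = np.cumsum(w * centers)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / (1 - omega0)
        sigma_b = omega0 * (1 - omega0) * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)
    return float(edges[int(np.argmax(sigma_b)) + 1])


@dataclass
class Mask:
    data: np.ndarray           # boolean volume
    geometry: GridGeometry
    provenance: str            # "threshold" | "refined" | "external"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != tuple(self.geometry.shape):
            raise ValueError("mask shape does not match geometry")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.data, self.geometry, "mask")


@dataclass
class QCReport:
    subject_id: str
    marrow_voxel_count: int
    marrow_to_muscle_b900_ratio: float
    segmentation_ok: bool


def threshold_segment(cdwi: ImageVolume, threshold: float | str = "auto",
                      largest_component: bool = False,
                      within: np.ndarray | None = None) -> tuple[Mask, float]:
    """Threshold the computed high-b image; returns (mask, threshold used).

    ``threshold="auto"`` computes Otsu's threshold over the positive-intensity
    histogram (256 bins). Otsu assumes two classes; a whole-body computed
    high-b field has three (air, body, marrow), so callers should pass a body
    mask as ``within`` to restrict the histogram (the resulting mask is also
    intersected with it). An image with no positive voxels yields an empty
    mask with threshold inf (QC catches it downstream).
    """
    data = cdwi.data
    sel = np.isfinite(data) & (data > 0)
    if within is not None:
        sel &= within
    if threshold == "auto":
        vals = data[sel]
        if vals.size == 0 or np.ptp(vals) == 0:
            log.warning("auto-threshold failed: no positive intensity spread")
            return Mask(np.zeros(data.shape, bool), cdwi.geometry, "threshold"), float("inf")
        thr = otsu_threshold(vals, nbins=256)
    else:
        thr = float(threshold)
    mask = (np.nan_to_num(data, nan=-np.inf) > thr)
    if within is not None:
        mask &= within
    if largest_component and mask.any():
        lab, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    log.debug("threshold %.2f selected %d voxels", thr, int(mask.sum()))
    return Mask(mask, cdwi.geometry, "threshold"), thr


def body_mask_from_total(total: ImageVolume) -> np.ndarray:
    """Body support from the Dixon total (Fat + Water) signal.

    Tissue has near-constant total Dixon signal while air has only the noise
    floor, so the histogram is reliably bimodal; with a noiseless background
    (no spread among positives) every positive voxel is body.
    """
    data = total.data
    finite = np.isfinite(data)
    vals = data[finite & (data > 0)]
    if vals.size == 0:
        return np.zeros(data.shape, bool)
    if np.ptp(vals) < 1e-6 * max(1.0, abs(float(vals[0]))):
        return finite & (data > 0)
    thr = otsu_threshold(vals, nbins=256)
    return finite & (data > thr)


def refine_mask(mask: Mask, adc: ImageVolume, ff: ImageVolume,
                adc_max: float = 1000.0, ff_min: float = 15.0
                ) -> tuple[Mask, dict]:
    """Keep in-mask voxels with valid ADC <= adc_max and valid %FF >= ff_min.

    Returns the refined mask and per-rule exclusion counts (a voxel failing
    both rules is counted under both; ``excluded`` is the union).
    """
    require_same_grid(mask.as_volume(), adc, "mask refinement")
    require_same_grid(adc, ff, "mask refinement")
    with np.errstate(invalid="ignore"):
        adc_ok = np.isfinite(adc.data) & (adc.data <= adc_max)
        ff_ok = np.isfinite(ff.data) & (ff.data >= ff_min)
    keep = mask.data & adc_ok & ff_ok
    counts = {
        "input": mask.count,
        "kept": int(keep.sum()),
        "excluded": int((mask.data & ~(adc_ok & ff_ok)).sum()),
        "excluded_adc": int((mask.data & ~adc_ok).sum()),
        "excluded_ff": int((mask.data & ~ff_ok).sum()),
    }
    log.debug("refinement: %(input)d -> %(kept)d voxels "
              "(ADC rule %(excluded_adc)d, FF rule %(excluded_ff)d)", counts)
    return Mask(keep, mask.geometry, "refined"), counts


def qc_subject(subject_id: str, mask: Mask, b900: ImageVolume,
               muscle_median_b900: float, min_voxels: int = 100,
               min_ratio: float = 1.0) -> QCReport:
    """Flag segmentations that are too small or whose marrow signal is not
    hyperintense relative to muscle (the failure phenotype of threshold
    segmentation on fatty, hypointense marrow)."""
    if muscle_median_b900 <= 0:
        raise ValueError("muscle median b900 must be positive")
    n = mask.count
    if n:
        ratio = float(np.median(b900.data[mask.data]) / muscle_median_b900)
    else:
        ratio = 0.0
    ok = (n >= min_voxels) and (ratio >= min_ratio)
    return QCReport(subject_id=subject_id, marrow_voxel_count=n,
                    marrow_to_muscle_b900_ratio=ratio, segmentation_ok=bool(ok))
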