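"""Muscle normalization and per-subject summary statistics.

The psoas-muscle mask provides a per-subject, per-b-value reference signal;
dividing each DW image by the median muscle signal at the same b-value yields
the dimensionless nSI maps. Per-subject summaries are the medians of %FF,
nSI_b50, nSI_b900 and ADC over the *same* refined-mask voxel set.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .geometry import ImageVolume, require_same_grid
from .marrowseg import Mask
from .synthcohort import SubjectMeta


class ProcessingError(RuntimeError):
    """A subject that cannot be measured (empty mask, unusable reference)."""


@dataclass
class SubjectMeasurements:
    subject_id: str
    median_ff: float            # %
    median_nsi_b50: float       # dimensionless
    median_nsi_b900: float      # dimensionless
    median_adc: float           # um^2/s
    marrow_voxels: int
    muscle_median_b50: float    # signal units
    muscle_median_b900: float

    def as_dict(self) -> dict:
        return asdict(self)


def muscle_medians(b50: ImageVolume, b900: ImageVolume,
                   muscle_mask: Mask) -> tuple[float, float]:
    """Median muscle signal per b-value over all mask voxels (all stations).

    Even-count medians use the mid-mean convention (mean of the two central
    order statistics).
    """
    require_same_grid(b50, b900, "muscle medians")
    require_same_grid(b50, muscle_mask.as_volume(), "muscle medians")
    if not muscle_mask.data.any():
        raise ProcessingError("empty muscle mask: subject unusable")
    return (float(np.median(b50.data[muscle_mask.data])),
            float(np.median(b900.data[muscle_mask.data])))


def normalize_si(dwi: ImageVolume, muscle_median: float) -> ImageVolume:
    """Voxelwise signal divided by the muscle median at the same b-value."""
    if muscle_median <= 0:
        raise ProcessingError(f"non-positive muscle median ({muscle_median})")
    return ImageVolume(dwi.data / muscle_median, dwi.geometry, "nsi")


def subject_summary(adc: ImageVolume, ff: ImageVolume,
                    nsi50: ImageVolume, nsi900: ImageVolume,
                    refined: Mask, meta: SubjectMeta,
                    muscle_b50: float, muscle_b900: float) -> SubjectMeasurements:
    """Medians of all four parameters over the identical refined-mask voxels."""
    for vol in (ff, nsi50, nsi900):
        require_same_grid(adc, vol, "subject summary")
    if not refined.data.any():
        raise ProcessingError("empty refined mask: routed to QC")
    idx = refined.data
    values = {name: np.asarray(v.data[idx], dtype=float)
              for name, v in (("ff", ff), ("adc", adc),
                              ("nsi50", nsi50), ("nsi900", nsi900))}
    for name, arr in values.items():
        if not np.all(np.isfinite(arr)):
            raise ProcessingError(f"non-finite {name} values inside refined mask")
    return SubjectMeasurements(
        subject_id=meta.subject_id,
        median_ff=float(np.median(values["ff"])),
        median_nsi_b50=float(np.median(values["nsi50"])),
        median_nsi_b900=float(np.median(values["nsi900"])),
        median_adc=float(np.median(values["adc"])),
        marrow_voxels=int(idx.sum()),
        muscle_median_b50=muscle_b50,
        muscle_median_b900=muscle_b900,
    )
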