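"""Optional DICOM series reader.

Maps ImagePositionPatient / ImageOrientationPatient / PixelSpacing onto the
package's grid geometry. Slices are ordered by their projection onto the
slice normal (not by InstanceNumber, which may be shuffled); inconsistent
in-plane geometry across the series is a geometry error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom

from .geometry import GeometryError, GridGeometry, ImageVolume


def read_dicom_series(series_dir, channel: str = "b900") -> ImageVolume:
    paths = sorted(Path(series_dir).glob("*.dcm"))
    if not paths:
        raise FileNotFoundError(f"no DICOM files under {series_dir}")
    slices = [pydicom.dcmread(str(p)) for p in paths]

    ref = slices[0]
    iop = np.array(ref.ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]           # along columns / rows of the image
    normal = np.cross(row_dir, col_dir)
    ps = [float(v) for v in ref.PixelSpacing]      # (row spacing, col spacing)

    for ds in slices[1:]:
        if (not np.allclose(ds.ImageOrientationPatient, iop, atol=1e-6)
                or not np.allclose([float(v) for v in ds.PixelSpacing], ps)):
            raise GeometryError("inconsistent geometry within DICOM series")

    slices.sort(key=lambda ds: float(
        np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))))
    zpos = np.array([np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))
                     for ds in slices])
    if len(slices) > 1:
        dz = np.diff(zpos)
        if np.ptp(dz) > 1e-3:
            raise GeometryError("non-uniform slice spacing in DICOM series")
        slice_spacing = float(np.mean(dz))
    else:
        slice_spacing = float(getattr(ref, "SliceThickness", 1.0))

    # pixel_array is [row, col]; our data axes are [x=col-direction? no:
    # axis 0 follows row_dir (x), axis 1 follows col_dir (y)] -> transpose.
    data = np.stack([ds.pixel_array.T for ds in slices], axis=2).astype(np.float64)
    slope = float(getattr(ref, "RescaleSlope", 1.0))
    intercept = float(getattr(ref, "RescaleIntercept", 0.0))
    data = data * slope + intercept

    R = np.column_stack([row_dir, col_dir, normal])
    geom = GridGeometry(
        origin=tuple(np.array(slices[0].ImagePositionPatient, dtype=float)),
        spacing=(ps[1], ps[0], slice_spacing),   # col spacing is along row_dir
        shape=data.shape,
        orientation=tuple(map(tuple, R)))
    return ImageVolume(data, geom, channel)
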