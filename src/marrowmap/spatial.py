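"""Grid alignment: Dixon-to-DWI resampling and station stacking.

The alignment policy mirrors how multi-station maps are projected between
sequences using only header geometry: for every target slice, the source
slice whose center is nearest along the slice axis is selected (no through-
plane interpolation); within the plane, values are interpolated bilinearly
(continuous maps) or by nearest neighbor (masks, labels). A target slice
with no source slice center within half the source slice thickness (+0.01 mm
tolerance) is marked invalid, never extrapolated. Out-of-extent in-plane
voxels are likewise invalid (NaN).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import GeometryError, GridGeometry, ImageVolume

SLICE_MATCH_TOL_MM = 0.01


def resample_to_grid(src: ImageVolume, target: GridGeometry,
                     mode: str = "linear") -> ImageVolume:
    """Resample ``src`` onto ``target`` (same orientation required).

    mode="linear" for continuous maps, "nearest" for categorical data.
    Returns float data with NaN at invalid voxels; nearest-mode resampling of
    a boolean mask returns a boolean mask (invalid -> False).
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    g = src.geometry
    if not g.same_orientation(target, tol=1e-3):
        raise GeometryError("resampling requires matching grid orientations")

    # Offset of the target origin in the shared grid frame.
    delta = g.R.T @ (np.asarray(target.origin) - np.asarray(g.origin))

    # Fractional source indices of target voxel centers, per axis.
    fidx = [(delta[a] + np.arange(target.shape[a]) * target.spacing[a])
            / g.spacing[a] for a in range(3)]

    # Slice axis: snap to the nearest source slice, reject beyond tolerance.
    zf = fidx[2]
    zi = np.rint(zf).astype(int)
    dist_mm = np.abs(zf - zi) * g.spacing[2]
    in_range = (zi >= 0) & (zi < g.shape[2])
    matched = in_range & (dist_mm <= g.spacing[2] / 2 + SLICE_MATCH_TOL_MM)
    zi_safe = np.clip(zi, 0, g.shape[2] - 1)

    was_bool = src.data.dtype == bool
    data = src.data.astype(np.float64)
    coords = np.stack(np.broadcast_arrays(
        fidx[0][:, None, None], fidx[1][None, :, None],
        zi_safe[None, None, :].astype(float)))
    order = 1 if mode == "linear" else 0
    out = map_coordinates(data, coords.reshape(3, -1), order=order,
                          mode="constant", cval=np.nan).reshape(target.shape)
    out[:, :, ~matched] = np.nan

    if was_bool and mode == "nearest":
        out = np.nan_to_num(out, nan=0.0).astype(bool)
    return ImageVolume(out, target, src.channel)


def stack_stations(volumes: list[ImageVolume]) -> ImageVolume:
    """Concatenate contiguous stations along the slice axis.

    Stations must share in-plane geometry and be ordered by slice-axis
    position; the inter-station gap or overlap must not exceed half a slice
    thickness (the emulated acquisitions are contiguous).
    """
    if not volumes:
        raise ValueError("no stations to stack")
    if len(volumes) == 1:
        return volumes[0]
    first = volumes[0].geometry
    z_prev_end = None
    for v in volumes:
        g = v.geometry
        if g.shape[:2] != first.shape[:2] or not np.allclose(
                g.spacing, first.spacing, atol=1e-6):
            raise GeometryError("stations differ in in-plane geometry or spacing")
        if not g.same_orientation(first):
            raise GeometryError("stations differ in orientation")
        o = g.R.T @ np.asarray(g.origin)
        o0 = first.R.T @ np.asarray(first.origin)
        if not np.allclose(o[:2], o0[:2], atol=1e-6):
            raise GeometryError("stations differ in in-plane origin")
        z0 = o[2]
        if z_prev_end is not None:
            gap = z0 - z_prev_end            # distance from expected next center
            if abs(gap) > g.spacing[2] / 2:
                raise GeometryError(
                    f"station gap/overlap {gap:+.2f} mm exceeds half a slice "
                    f"thickness ({g.spacing[2] / 2:.2f} mm)")
            if z0 <= z_prev_end - g.spacing[2]:
                raise GeometryError("stations not ordered by slice-axis position")
        z_prev_end = z0 + g.shape[2] * g.spacing[2]
    data = np.concatenate([v.data for v in volumes], axis=2)
    geom = GridGeometry(origin=first.origin, spacing=first.spacing,
                        shape=(first.shape[0], first.shape[1], data.shape[2]),
                        orientation=first.orientation)
    return ImageVolume(data, geom, volumes[0].channel)
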