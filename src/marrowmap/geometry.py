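"""Image grids and volumes.

All geometry lives in a single patient-space convention (LPS, the DICOM
convention). A grid is axis-aligned in that frame through its direction-cosine
matrix; voxel ``(i, j, k)`` has its *center* at ``origin + R @ (index * spacing)``
with 0-based indices. Data arrays are indexed ``[i, j, k]`` with axis 2 the
slice (superior-inferior) axis.

NIfTI files store RAS affines; conversion happens at the I/O boundary so all
in-memory math is single-convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

#: Allowed channel tags for ImageVolume.
CHANNELS = (
    "b50", "b900", "dixon_fat", "dixon_water",
    "adc", "ff", "cdwi", "nsi", "total", "mask", "labels",
)

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])   # homogeneous-affine flip


class GeometryError(ValueError):
    """Raised when grids are incompatible (orientation, spacing, coverage)."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular 3D sampling grid in patient (LPS) coordinates.

    origin
        Physical position (mm) of the center of voxel (0, 0, 0).
    spacing
        Voxel center-to-center distance (mm) along each grid axis; also the
        nominal slice thickness along axis 2 (contiguous slices).
    shape
        Number of voxels along each axis.
    orientation
        3x3 direction-cosine matrix; columns are the patient-space directions
        of the grid axes. Must be orthonormal.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    orientation: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        sp = np.asarray(self.spacing, dtype=float)
        if not np.all(sp > 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        R = self.R
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise GeometryError("orientation matrix is not orthonormal")
        if any(int(n) <= 0 for n in self.shape):
            raise GeometryError(f"shape must be positive, got {self.shape}")

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.orientation, dtype=float)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Grid-frame coordinate (mm) of voxel centers along one axis."""
        o = self.R.T @ np.asarray(self.origin, dtype=float)
        return o[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Patient-space coordinates of all voxel centers, as 3 broadcastable
        arrays shaped like the grid (valid for any orthonormal orientation)."""
        idx = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        off = np.stack([idx[a] * self.spacing[a] for a in range(3)], axis=-1)
        pts = np.asarray(self.origin) + off @ self.R.T
        return pts[..., 0], pts[..., 1], pts[..., 2]

    def same_orientation(self, other: "GridGeometry", tol: float = 1e-3) -> bool:
        return bool(np.allclose(self.R, other.R, atol=tol))

    @property
    def slice_extent(self) -> tuple[float, float]:
        """Physical span covered by slices along axis 2, including half-voxels."""
        z0 = float((self.R.T @ np.asarray(self.origin))[2])
        return (z0 - self.spacing[2] / 2,
                z0 + (self.shape[2] - 0.5) * self.spacing[2])

    def to_affine_lps(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.R @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @classmethod
    def from_affine_lps(cls, affine: np.ndarray, shape) -> "GridGeometry":
        M = np.asarray(affine, dtype=float)[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        R = M / spacing
        return cls(origin=tuple(np.asarray(affine)[:3, 3]),
                   spacing=tuple(spacing),
                   shape=tuple(int(n) for n in shape),
                   orientation=tuple(map(tuple, R)))


@dataclass
class ImageVolume:
    """A 3D scalar field plus its grid; carrier for every image-like object
    in the pipeline (DW channels, Dixon channels, parameter maps, masks)."""

    data: np.ndarray
    geometry: GridGeometry
    channel: str = "mask"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.geometry.shape):
            raise GeometryError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    def with_data(self, data: np.ndarray, channel: str | None = None) -> "ImageVolume":
        return ImageVolume(data, self.geometry, channel or self.channel)

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        g, h = self.geometry, other.geometry
        return (g.shape == h.shape
                and np.allclose(g.origin, h.origin, atol=tol)
                and np.allclose(g.spacing, h.spacing, atol=tol)
                and g.same_orientation(h, tol=1e-3))


def require_same_grid(a: ImageVolume, b: ImageVolume, what: str = "operation") -> None:
    if not a.same_grid(b):
        raise GeometryError(f"{what} requires identical grids "
                            f"({a.channel} vs {b.channel})")


# ---------------------------------------------------------------------------
# NIfTI I/O (RAS on disk <-> LPS in memory)

def write_nifti(vol: ImageVolume, path) -> None:
    affine_ras = _LPS_TO_RAS @ vol.geometry.to_affine_lps()
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), affine_ras)
    img.header.set_zooms(vol.geometry.spacing)
    nib.save(img, str(path))


def read_nifti(path, channel: str) -> ImageVolume:
    img = nib.load(str(path))
    affine_lps = _LPS_TO_RAS @ img.affine
    geom = GridGeometry.from_affine_lps(affine_lps, img.shape)
    data = np.asanyarray(img.dataobj)
    if channel == "mask":
        data = data.astype(bool)
    return ImageVolume(data, geom, channel)
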