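"""Sphere ROIs on a regular voxel grid.

Region-of-interest analysis averages the signal over every voxel whose
*centre* falls within a fixed radius of a world-space (MNI-style, mm)
coordinate; the default is an 8 mm sphere at the posterior medial frontal
cortex peak (x = 2, y = 16, z = 46) used in interference-processing studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "ROISpec", "sphere_voxels", "roi_average"]


@dataclass
class GridSpec:
    """Axis-aligned voxel grid in world (mm) coordinates.

    The default is a small 20 x 20 x 16 grid at 3.75 x 3.75 x 3.0 mm,
    positioned so that the default ROI centre (2, 16, 46) coincides with the
    centre of voxel (10, 10, 8).
    """

    shape: tuple[int, int, int] = (20, 20, 16)
    voxel_size: tuple[float, float, float] = (3.75, 3.75, 3.0)
    origin: tuple[float, float, float] = (-35.5, -21.5, 22.0)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (axis-aligned)."""
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (nx*ny*nz, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)


@dataclass
class ROISpec:
    """Sphere ROI: all voxels whose centre lies within `radius` of `center`."""

    center: tuple[float, float, float] = (2.0, 16.0, 46.0)  # mm
    radius: float = 8.0  # mm

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


def sphere_voxels(roi: ROISpec, grid: GridSpec) -> np.ndarray:
    """Voxel indices inside the sphere.

    Returns an (n, 3) integer array of voxel indices whose centre-to-centre
    Euclidean distance to ``roi.center`` is at most ``roi.radius``.  An empty
    selection triggers a warning rather than an error.
    """
    centers = grid.voxel_centers()
    d = np.linalg.norm(centers - np.asarray(roi.center), axis=1)
    inside = np.flatnonzero(d <= roi.radius)
    if inside.size == 0:
        warnings.warn(
            f"sphere ROI at {roi.center} with radius {roi.radius} mm contains "
            "no voxel centres",
            stacklevel=2,
        )
    idx = np.indices(grid.shape).reshape(3, -1).T
    return idx[inside]


def roi_average(data: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Unweighted mean time course over the selected voxels.

    Parameters
    ----------
    data
        4-D array ``(t, nx, ny, nz)`` or 2-D array ``(t, n_voxels_flat)``.
    voxels
        ``(n, 3)`` voxel indices (from :func:`sphere_voxels`) for 4-D input,
        or a 1-D index array for 2-D input.
    """
    data = np.asarray(data)
    voxels = np.asarray(voxels)
    if data.ndim == 4:
        return data[:, voxels[:, 0], voxels[:, 1], voxels[:, 2]].mean(axis=1)
    if data.ndim == 2:
        return data[:, voxels.ravel()].mean(axis=1)
    raise ValueError("data must be (t, nx, ny, nz) or (t, n_voxels)")
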