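"""Tomographic volume container.

Conventions used throughout the package:

* voxel grids are numpy arrays indexed ``grid[z, y, x]`` (the MRC section
  order, z slowest);
* physical coordinates are ``[x, y, z]`` vectors in nanometres;
* ``origin`` is the physical coordinate of the centre of voxel (0, 0, 0);
* the electron beam runs along z, the tilt axis along y, and the support
  plane is a constant-z plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TomogramVolume:
    """A 3D scalar grid with physical metadata.

    Parameters
    ----------
    grid:
        3D array indexed ``[z, y, x]``.
    pixel_size:
        Isotropic voxel edge in nm. Must be positive.
    tilt_range:
        Half-range of the acquisition tilt series in degrees
        (``None`` for untilted / synthetic noise-free volumes).
    origin:
        Physical nm coordinate ``[x, y, z]`` of voxel (0, 0, 0).
    """

    grid: np.ndarray
    pixel_size: float
    tilt_range: float | None = None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got shape {self.grid.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.tilt_range is not None and not 0 < self.tilt_range <= 90:
            raise ValueError(f"tilt_range must lie in (0, 90], got {self.tilt_range}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def extent_nm(self) -> np.ndarray:
        """Physical size ``[x, y, z]`` of the volume in nm."""
        nz, ny, nx = self.grid.shape
        return np.array([nx, ny, nz], dtype=float) * self.pixel_size

    def world_to_voxel(self, point_nm: np.ndarray) -> np.ndarray:
        """Map a physical ``[x, y, z]`` point to fractional voxel indices
        ``[ix, iy, iz]``."""
        return (np.asarray(point_nm, dtype=float) - self.origin) / self.pixel_size

    def voxel_to_world(self, index_xyz: np.ndarray) -> np.ndarray:
        return np.asarray(index_xyz, dtype=float) * self.pixel_size + self.origin

    def contains_box(self, center_nm: np.ndarray, box_edge: int) -> bool:
        """True if a cubic box of ``box_edge`` voxels centred on the voxel
        nearest to ``center_nm`` lies fully inside the grid."""
        ix, iy, iz = np.rint(self.world_to_voxel(center_nm)).astype(int)
        half = box_edge // 2
        nz, ny, nx = self.grid.shape
        return (
            ix - half >= 0 and ix - half + box_edge <= nx
            and iy - half >= 0 and iy - half + box_edge <= ny
            and iz - half >= 0 and iz - half + box_edge <= nz
        )
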