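"""Cartesian voxel grids centered on the ultrasound focal center.

The simulator uses a right-handed coordinate system with the origin at the
focal center and +Z pointing along the ultrasound propagation direction
(top of the tissue toward the bottom).  Grids always contain the origin as
a sample point, so sample counts per axis are odd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CartesianGrid"]


@dataclass(frozen=True)
class CartesianGrid:
    """Regular voxel grid symmetric about the focal center.

    Parameters
    ----------
    dx, dy, dz:
        Voxel spacings in meters.
    Lx, Ly, Lz:
        Half-extents in meters.  The grid spans ``[-L, +L]`` per axis with
        an odd number of samples so the origin is always a grid point.
    """

    dx: float
    dy: float
    dz: float
    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"spacing {name} must be positive")
        for name in ("Lx", "Ly", "Lz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"half-extent {name} must be positive")

    def _axis(self, spacing: float, half_extent: float) -> np.ndarray:
        n_half = int(round(half_extent / spacing))
        return spacing * np.arange(-n_half, n_half + 1)

    @property
    def x(self) -> np.ndarray:
        return self._axis(self.dx, self.Lx)

    @property
    def y(self) -> np.ndarray:
        return self._axis(self.dy, self.Ly)

    @property
    def z(self) -> np.ndarray:
        return self._axis(self.dz, self.Lz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.z.size)

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def center_index(self) -> tuple[int, int, int]:
        return (self.x.size // 2, self.y.size // 2, self.z.size // 2)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable coordinate arrays (indexing='ij')."""
        return np.meshgrid(self.x, self.y, self.z, indexing="ij", sparse=True)

    def points(self) -> np.ndarray:
        """All voxel centers as an ``(n, 3)`` array (C order over x, y, z)."""
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)

    def index_of(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest ``point`` (meters)."""
        px, py, pz = point
        ix = int(round(px / self.dx)) + self.x.size // 2
        iy = int(round(py / self.dy)) + self.y.size // 2
        iz = int(round(pz / self.dz)) + self.z.size // 2
        if not (0 <= ix < self.x.size and 0 <= iy < self.y.size and 0 <= iz < self.z.size):
            raise ValueError(f"point {point} lies outside the grid")
        return ix, iy, iz
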