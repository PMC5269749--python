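"""3D attenuation volumes on regular voxel grids.

The package convention throughout: arrays are indexed ``(z, y, x)`` (one
TIFF page per z-slice), physical vectors are written ``(x, y, z)``, all
lengths are in millimetres and the voxel grid is isotropic.  ``z`` is the
rotation-axis / specimen-normal direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume3D", "GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Regular, isotropic voxel grid.

    Parameters
    ----------
    shape :
        ``(nz, ny, nx)`` voxel counts.
    voxel_size :
        Edge length of a voxel in mm.
    origin :
        Physical ``(x, y, z)`` coordinate of the *center* of voxel
        ``(0, 0, 0)`` in mm.  The default centers the grid on the
        rotation axis, i.e. the physical grid center sits at the origin.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.origin is None:
            nz, ny, nx = self.shape
            v = self.voxel_size
            object.__setattr__(
                self,
                "origin",
                (-(nx - 1) / 2 * v, -(ny - 1) / 2 * v, -(nz - 1) / 2 * v),
            )

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical ``(x, y, z)`` edge lengths in mm (voxel-count × size)."""
        nz, ny, nx = self.shape
        return (nx * self.voxel_size, ny * self.voxel_size, nz * self.voxel_size)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates ``(X, Y, Z)`` broadcast to ``shape``."""
        nz, ny, nx = self.shape
        ox, oy, oz = self.origin
        x = ox + self.voxel_size * np.arange(nx)
        y = oy + self.voxel_size * np.arange(ny)
        z = oz + self.voxel_size * np.arange(nz)
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        return X, Y, Z


@dataclass
class Volume3D:
    """A scalar field of linear attenuation coefficients μ (1/mm).

    ``data`` is indexed ``(z, y, x)``.  All values must be finite.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.origin is None:
            self.origin = GridSpec(self.data.shape, self.voxel_size).origin
        self.origin = tuple(float(c) for c in self.origin)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(tuple(self.data.shape), self.voxel_size, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on the same grid with replaced voxel values."""
        return Volume3D(data, self.voxel_size, self.origin, dict(self.meta))

    def same_grid(self, other: "Volume3D", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size, other.voxel_size, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-9)
        )
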