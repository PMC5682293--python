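"""Volumetric containers and grid bookkeeping.

All volumes use (z, y, x) axis order with 0-based voxel indices. Physical
coordinates are attached to voxel *centers*: the coordinate of voxel ``i``
along an axis is ``(i - origin) * pitch`` in micrometres, where ``origin`` is
the (possibly fractional) index of the physical origin. By default the origin
sits at the geometric center of the grid, which places the mirror plane
``z = -x tan(theta)`` through the middle of the volume so that both the real
and the virtual (reflected) half-spaces are representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Volume", "GridSpec", "center_origin"]


def center_origin(shape: tuple[int, int, int]) -> tuple[float, float, float]:
    """Fractional voxel index of the grid center, per axis."""
    return tuple((n - 1) / 2.0 for n in shape)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a sampling grid without pixel data.

    Parameters
    ----------
    shape : (nz, ny, nx) voxel counts.
    pitch : (pz, py, px) voxel pitch in micrometres.
    origin : fractional voxel index of the physical origin; defaults to the
        grid center.
    """

    shape: tuple[int, int, int]
    pitch: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if len(self.shape) != 3 or len(self.pitch) != 3:
            raise ValueError("GridSpec is three-dimensional (z, y, x)")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(p <= 0 for p in self.pitch):
            raise ValueError("voxel pitch must be positive")
        if self.origin is None:
            object.__setattr__(self, "origin", center_origin(self.shape))

    def coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (um) of the voxel centers along ``axis``."""
        n = self.shape[axis]
        return (np.arange(n) - self.origin[axis]) * self.pitch[axis]

    def zeros(self, dtype=np.float64) -> "Volume":
        return Volume(np.zeros(self.shape, dtype=dtype), self.pitch, self.origin)


@dataclass
class Volume:
    """A 3D scalar intensity grid with voxel pitch and coordinate frame.

    ``frame`` names the coordinate system: ``fixed`` (object space, camera
    looking down z, mirror through the origin), ``camera_primed`` (raw
    stage-scan data as seen by the detector) or ``coverslip``.
    """

    data: np.ndarray
    pitch: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None
    frame: str = "fixed"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D (z, y, x)")
        self.pitch = tuple(float(p) for p in self.pitch)
        if any(p <= 0 for p in self.pitch):
            raise ValueError("voxel pitch must be positive")
        if self.origin is None:
            self.origin = center_origin(self.data.shape)
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.pitch, self.origin)

    def coords(self, axis: int) -> np.ndarray:
        return self.grid.coords(axis)

    def with_data(self, data: np.ndarray, frame: str | None = None) -> "Volume":
        """A new Volume on the same grid holding ``data``."""
        return Volume(data, self.pitch, self.origin, frame or self.frame)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.pitch, self.origin, self.frame)

    def total(self) -> float:
        return float(self.data.sum())
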