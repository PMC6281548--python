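"""Voxel grids and the world <-> voxel mapping.

Axis convention: image arrays are indexed ``[ix, iy]`` (2D) or ``[ix, iy, iz]``
(3D), with ``z`` the axial (scanner bore) direction.  World coordinates are in
millimetres; ``origin`` is the world position of the centre of voxel
``(0, 0[, 0])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """A regular 2D or 3D voxel grid.

    Parameters
    ----------
    shape
        Voxel counts per axis, ``(nx, ny)`` or ``(nx, ny, nz)``.
    voxel_size
        Voxel edge lengths in mm per axis, same length as ``shape``.
    origin
        World (mm) position of the centre of voxel ``(0, 0[, 0])``.
    """

    shape: tuple[int, ...]
    voxel_size: tuple[float, ...]
    origin: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(shape) not in (2, 3):
            raise ValueError("grid must be 2D or 3D")
        if len(voxel_size) != len(shape):
            raise ValueError("voxel_size must match shape dimensionality")
        if any(n < 1 for n in shape):
            raise ValueError("shape entries must be >= 1")
        if any(v <= 0 for v in voxel_size):
            raise ValueError("voxel sizes must be positive")
        origin = self.origin
        if origin is None:
            # centre the grid on the world origin
            origin = tuple(
                -(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size)
            )
        origin = tuple(float(o) for o in origin)
        if len(origin) != len(shape):
            raise ValueError("origin must match shape dimensionality")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel_size)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.voxel_size[axis] * np.arange(self.shape[axis])

    def coordinate_images(self) -> tuple[np.ndarray, ...]:
        """Dense voxel-centre coordinate arrays, one per axis, each of ``shape``."""
        axes = [self.axis_coords(a) for a in range(self.ndim)]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine (NIfTI convention)."""
        aff = np.eye(4)
        for a in range(self.ndim):
            aff[a, a] = self.voxel_size[a]
            aff[a, 3] = self.origin[a]
        return aff

    @classmethod
    def from_affine(cls, shape: tuple[int, ...], affine: np.ndarray) -> "ImageGrid":
        ndim = len(shape)
        voxel_size = tuple(float(affine[a, a]) for a in range(ndim))
        origin = tuple(float(affine[a, 3]) for a in range(ndim))
        return cls(shape=tuple(shape), voxel_size=voxel_size, origin=origin)
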