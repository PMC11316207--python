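"""Voxel-grid geometry shared by every image, mask and atlas in the pipeline.

All physical quantities in this package are expressed in millimetres; arrays
use a fixed (x, y, z) axis order with 0-based indices.  The default grid is
the acquisition grid of the ex vivo T2-weighted protocol: 0.6 x 0.6 mm
in-plane with 1.5 mm slices, i.e. a 0.54 mm^3 voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: spacing comparison tolerance (mm) when deciding two grids match
SPACING_TOL_MM = 1e-4

DEFAULT_SPACING_MM = (0.6, 0.6, 1.5)


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical spacing of an anisotropic 3D voxel grid.

    Parameters
    ----------
    spacing_mm : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres; all positive.
    """

    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM

    def __post_init__(self) -> None:
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(not np.isfinite(s) or s <= 0 for s in sp):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm!r}")
        object.__setattr__(self, "spacing_mm", sp)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    def same_grid(self, other: "VoxelGeometry") -> bool:
        return bool(np.all(np.abs(self.spacing - other.spacing) <= SPACING_TOL_MM))

    def affine(self) -> np.ndarray:
        """Diagonal NIfTI affine mapping voxel indices to mm coordinates."""
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.spacing_mm
        return a


def check_same_grid(a, b, what: str = "volumes") -> None:
    """Raise ``ValueError`` unless two gridded objects share shape and spacing."""
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"{what} have different shapes: {a.grid.shape} vs {b.grid.shape}")
    if not a.geometry.same_grid(b.geometry):
        raise ValueError(
            f"{what} have different spacings: "
            f"{a.geometry.spacing_mm} vs {b.geometry.spacing_mm}"
        )
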