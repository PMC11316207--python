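"""Steerable Gaussian-derivative features.

Per scale: the Gaussian-smoothed image, nine steered first-order responses
g . v and nine steered second-order responses v^T H v, one per orientation
v — 19 maps.  Orientations are unit vectors; steering is analytic (the
oriented response is assembled from the axis-aligned derivative basis),
which is mathematically identical to filtering with rotated kernels.
"""

from __future__ import annotations

import numpy as np

from ..geometry import VoxelGeometry
from .derivatives import gaussian_gradient, gaussian_hessian, gaussian_smooth

_SQ2 = 1.0 / np.sqrt(2.0)

#: default 9 orientations: the 3 grid axes and the 6 face diagonals reduced
#: to one hemisphere — a fixed, symmetric, reproducible coverage.
DEFAULT_ORIENTATIONS: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (_SQ2, _SQ2, 0.0),
    (_SQ2, -_SQ2, 0.0),
    (_SQ2, 0.0, _SQ2),
    (_SQ2, 0.0, -_SQ2),
    (0.0, _SQ2, _SQ2),
    (0.0, _SQ2, -_SQ2),
)


def check_orientations(orientations) -> np.ndarray:
    arr = np.asarray(orientations, dtype=float)
    if arr.shape != (9, 3):
        raise ValueError(f"expected 9 orientation vectors, got shape {arr.shape}")
    norms = np.linalg.norm(arr, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("orientation vectors must have unit norm")
    return arr


def steerable_features(
    grid: np.ndarray,
    sigma_mm: float,
    geometry: VoxelGeometry,
    orientations=DEFAULT_ORIENTATIONS,
) -> tuple[list[np.ndarray], list[str]]:
    """Return the 19 steerable-filter maps and their names for one scale."""
    vs = check_orientations(orientations)
    maps: list[np.ndarray] = [gaussian_smooth(grid, sigma_mm, geometry)]
    names = [f"sf-{sigma_mm:g}mm-gauss"]

    grad = gaussian_gradient(grid, sigma_mm, geometry)
    for k, v in enumerate(vs):
        maps.append(v[0] * grad[0] + v[1] * grad[1] + v[2] * grad[2])
        names.append(f"sf-{sigma_mm:g}mm-d1-o{k}")

    hess = gaussian_hessian(grid, sigma_mm, geometry)
    for k, v in enumerate(vs):
        r = np.zeros_like(grid, dtype=np.float64)
        for i in range(3):
            for j in range(3):
                key = (i, j) if i <= j else (j, i)
                r += v[i] * v[j] * hess[key]
        maps.append(r)
        names.append(f"sf-{sigma_mm:g}mm-d2-o{k}")
    return maps, names
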