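"""Frangi vesselness features from the scale-normalized Hessian.

Per scale, five maps: the three Hessian eigenvalues sorted by magnitude
(|l1| <= |l2| <= |l3|), the bright-tube vesselness (perivascular spaces are
hyperintense in T2, so a bright tube has l2, l3 strongly negative) and the
second-order structureness S (Frobenius norm of the Hessian).
"""

from __future__ import annotations

import numpy as np

from ..geometry import VoxelGeometry
from .derivatives import (
    gaussian_hessian,
    hessian_matrix_field,
    sorted_eigenvalues_by_magnitude,
)

FRANGI_ALPHA = 0.5
FRANGI_BETA = 0.5


def frangi_vesselness(ev: np.ndarray, alpha: float = FRANGI_ALPHA, beta: float = FRANGI_BETA) -> np.ndarray:
    """Bright-tube vesselness from magnitude-sorted eigenvalues (..., 3).

    The structureness cut-off c is half the maximum Frobenius norm over the
    volume (the usual adaptive choice); a flat volume yields all zeros.
    """
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    s = np.sqrt(l1**2 + l2**2 + l3**2)
    smax = float(s.max())
    if smax <= 0:
        return np.zeros(ev.shape[:-1])
    c = smax / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = np.abs(l2) / np.abs(l3)
        rb = np.abs(l1) / np.sqrt(np.abs(l2 * l3))
    ra = np.nan_to_num(ra, nan=0.0, posinf=0.0)
    rb = np.nan_to_num(rb, nan=0.0, posinf=0.0)
    v = (
        (1.0 - np.exp(-(ra**2) / (2 * alpha**2)))
        * np.exp(-(rb**2) / (2 * beta**2))
        * (1.0 - np.exp(-(s**2) / (2 * c**2)))
    )
    # bright structures only: both dominant curvatures must be negative
    v[(l2 > 0) | (l3 > 0)] = 0.0
    return v


def frangi_features(
    grid: np.ndarray, sigma_mm: float, geometry: VoxelGeometry
) -> tuple[list[np.ndarray], list[str]]:
    """Return the 5 Frangi-filter maps and their names for one scale."""
    h = gaussian_hessian(grid, sigma_mm, geometry, scale_normalized=True)
    ev = sorted_eigenvalues_by_magnitude(hessian_matrix_field(h))
    s = np.sqrt((ev**2).sum(axis=-1))
    v = frangi_vesselness(ev)
    maps = [ev[..., 0], ev[..., 1], ev[..., 2], v, s]
    base = f"ff-{sigma_mm:g}mm"
    names = [f"{base}-l1", f"{base}-l2", f"{base}-l3", f"{base}-vesselness", f"{base}-structureness"]
    return maps, names
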