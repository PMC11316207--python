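"""Optimally oriented flux (OOF) features.

The oriented-flux matrix at radius r collects, per voxel, the outward flux
of the (slightly smoothed) image gradient through the sphere of radius r,
projected on each orientation pair.  It is computed in the Fourier domain:
for spatial frequency k (cycles/mm, |k| = kn),

    F{Q_ij}(k) = -8 pi^2 r^2 * j1(2 pi r kn) * k_i k_j / kn * G_sigma(k) * I(k)

with the spherical Bessel function j1(x) = sin(x)/x^2 - cos(x)/x.  The
matrix is normalized by the sphere area (4 pi r^2), i.e. maps hold average
flux, which keeps responses comparable across radii.

Per radius, five maps: the three eigenvalues sorted ascending, the
bright-tube measure (geometric mean of the two most negative eigenvalues,
clamped at zero — for a bright tube the gradient points inwards and the two
cross-sectional eigenvalues are negative) and the Frobenius norm.
"""

from __future__ import annotations

import numpy as np

from ..geometry import VoxelGeometry


def _spherical_j1(x: np.ndarray) -> np.ndarray:
    """j1(x) = sin(x)/x^2 - cos(x)/x with the correct x -> 0 limit (0)."""
    out = np.zeros_like(x)
    nz = np.abs(x) > 1e-12
    xs = x[nz]
    out[nz] = np.sin(xs) / xs**2 - np.cos(xs) / xs
    return out


def oriented_flux_matrix(
    grid: np.ndarray,
    radius_mm: float,
    geometry: VoxelGeometry,
    sigma_mm: float | None = None,
) -> np.ndarray:
    """Average oriented-flux matrix field, shape (X, Y, Z, 3, 3)."""
    sp = geometry.spacing
    if radius_mm < min(sp):
        raise ValueError(f"OOF radius {radius_mm} mm is below the smallest spacing {min(sp)} mm")
    extents = np.asarray(grid.shape) * sp
    if radius_mm > min(extents) / 2:
        raise ValueError(
            f"OOF radius {radius_mm} mm exceeds half the smallest volume extent "
            f"({min(extents) / 2:.1f} mm)"
        )
    if sigma_mm is None:
        sigma_mm = float(min(sp))  # mild pre-smoothing for gradient stability

    freqs = [np.fft.fftfreq(n, d=d) for n, d in zip(grid.shape, sp)]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    kn2 = kx**2 + ky**2 + kz**2
    kn = np.sqrt(kn2)

    fimg = np.fft.fftn(grid.astype(np.float64))
    gauss = np.exp(-2 * np.pi**2 * sigma_mm**2 * kn2)
    with np.errstate(divide="ignore", invalid="ignore"):
        # -8 pi^2 r^2 j1(2 pi r kn) / kn, normalized by sphere area 4 pi r^2
        radial = np.where(kn > 0, -2 * np.pi * _spherical_j1(2 * np.pi * radius_mm * kn) / kn, 0.0)
    base = fimg * gauss * radial

    ks = (kx, ky, kz)
    q = np.empty(grid.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        for j in range(i, 3):
            comp = np.fft.ifftn(base * ks[i] * ks[j]).real
            q[..., i, j] = comp
            q[..., j, i] = comp
    return q


def oof_tube_measure(ev_ascending: np.ndarray) -> np.ndarray:
    """Geometric mean of the two most negative eigenvalues, clamped at 0."""
    a = np.maximum(-ev_ascending[..., 0], 0.0)
    b = np.maximum(-ev_ascending[..., 1], 0.0)
    return np.sqrt(a * b)


def oof_features(
    grid: np.ndarray, radius_mm: float, geometry: VoxelGeometry
) -> tuple[list[np.ndarray], list[str]]:
    """Return the 5 OOF maps and their names for one radius."""
    q = oriented_flux_matrix(grid, radius_mm, geometry)
    ev = np.linalg.eigvalsh(q)  # ascending
    frob = np.sqrt((ev**2).sum(axis=-1))
    tube = oof_tube_measure(ev)
    maps = [ev[..., 0], ev[..., 1], ev[..., 2], tube, frob]
    base = f"oof-{radius_mm:g}mm"
    names = [f"{base}-l1", f"{base}-l2", f"{base}-l3", f"{base}-tube", f"{base}-frobenius"]
    return maps, names
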