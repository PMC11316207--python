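"""Multi-scale filter-bank assembly.

The bank runs steerable (SF), Frangi (FF) and optimally-oriented-flux (OOF)
filters over configured scale lists on the normalized image, and again on
its white top-hat transform.  With the defaults (3 SF scales, 12 FF scales,
12 OOF radii) that is 19*3 + 5*12 + 5*12 = 177 maps per branch and 354 in
total.  Map order is deterministic: branch -> filter family -> scale ->
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import VoxelGeometry
from ..volume import IntensityVolume, white_tophat
from .frangi import frangi_features
from .oof import oof_features
from .steerable import DEFAULT_ORIENTATIONS, check_orientations, steerable_features

#: maps emitted per scale by each filter family
SF_MAPS_PER_SCALE = 19
FF_MAPS_PER_SCALE = 5
OOF_MAPS_PER_SCALE = 5


def _log_spaced(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(float(x) for x in np.geomspace(lo, hi, n))


@dataclass
class FilterBankConfig:
    """Scale lists and branch switches of the feature bank.

    Scales bracket the radii of perivascular spaces representable at
    0.6 mm in-plane resolution.  OOF radii start at the smallest voxel
    spacing (the filter is undefined below one voxel).
    """

    sf_sigmas_mm: tuple[float, ...] = (0.5, 1.0, 2.0)
    sf_orientations: tuple = DEFAULT_ORIENTATIONS
    ff_sigmas_mm: tuple[float, ...] = field(default_factory=lambda: _log_spaced(0.4, 3.0, 12))
    oof_radii_mm: tuple[float, ...] = field(default_factory=lambda: _log_spaced(0.6, 3.0, 12))
    use_tophat_branch: bool = True
    tophat_radius_mm: float = 1.2

    def __post_init__(self) -> None:
        check_orientations(self.sf_orientations)
        for name in ("sf_sigmas_mm", "ff_sigmas_mm", "oof_radii_mm"):
            scales = tuple(float(s) for s in getattr(self, name))
            if any(s <= 0 for s in scales):
                raise ValueError(f"{name} must be positive, got {scales}")
            if any(b <= a for a, b in zip(scales, scales[1:])):
                raise ValueError(f"{name} must be strictly increasing, got {scales}")
            setattr(self, name, scales)

    @property
    def feature_count(self) -> int:
        per_branch = (
            SF_MAPS_PER_SCALE * len(self.sf_sigmas_mm)
            + FF_MAPS_PER_SCALE * len(self.ff_sigmas_mm)
            + OOF_MAPS_PER_SCALE * len(self.oof_radii_mm)
        )
        return (2 if self.use_tophat_branch else 1) * per_branch


@dataclass
class FeatureStack:
    """Ordered set of co-registered 3D feature maps on one grid."""

    maps: np.ndarray  # (n_features, X, Y, Z), float32
    names: list[str]
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float32)
        if self.maps.ndim != 4:
            raise ValueError(f"expected (n, X, Y, Z) maps, got shape {self.maps.shape}")
        if self.maps.shape[0] != len(self.names):
            raise ValueError(
                f"{self.maps.shape[0]} maps but {len(self.names)} names"
            )
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("feature stack contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.maps.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


def _stack(maps: list[np.ndarray], names: list[str], geometry: VoxelGeometry) -> FeatureStack:
    return FeatureStack(np.stack([m.astype(np.float32) for m in maps]), names, geometry)


def steerable_stack(vol: IntensityVolume, sigma_mm: float, orientations=DEFAULT_ORIENTATIONS) -> FeatureStack:
    maps, names = steerable_features(vol.grid, sigma_mm, vol.geometry, orientations)
    return _stack(maps, names, vol.geometry)


def frangi_stack(vol: IntensityVolume, sigma_mm: float) -> FeatureStack:
    maps, names = frangi_features(vol.grid, sigma_mm, vol.geometry)
    return _stack(maps, names, vol.geometry)


def oof_stack(vol: IntensityVolume, radius_mm: float) -> FeatureStack:
    maps, names = oof_features(vol.grid, radius_mm, vol.geometry)
    return _stack(maps, names, vol.geometry)


def _branch_maps(vol: IntensityVolume, config: FilterBankConfig, prefix: str):
    maps: list[np.ndarray] = []
    names: list[str] = []
    for s in config.sf_sigmas_mm:
        m, n = steerable_features(vol.grid, s, vol.geometry, config.sf_orientations)
        maps += m
        names += [f"{prefix}-{x}" for x in n]
    for s in config.ff_sigmas_mm:
        m, n = frangi_features(vol.grid, s, vol.geometry)
        maps += m
        names += [f"{prefix}-{x}" for x in n]
    for r in config.oof_radii_mm:
        m, n = oof_features(vol.grid, r, vol.geometry)
        maps += m
        names += [f"{prefix}-{x}" for x in n]
    return maps, names


def save_feature_stack(stack: FeatureStack, path) -> None:
    """Persist a stack as one 4D NIfTI plus a JSON name manifest."""
    import json
    from pathlib import Path

    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(stack.maps, 0, -1), stack.geometry.affine())
    nib.save(img, str(path))
    with open(path.with_suffix("").with_suffix(".json"), "w") as fh:
        json.dump({"names": stack.names, "spacing_mm": stack.geometry.spacing_mm}, fh)


def load_feature_stack(path) -> FeatureStack:
    import json
    from pathlib import Path

    import nibabel as nib

    from ..geometry import VoxelGeometry as _VG

    path = Path(path)
    with open(path.with_suffix("").with_suffix(".json")) as fh:
        meta = json.load(fh)
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)
    return FeatureStack(
        np.moveaxis(data, -1, 0), meta["names"], _VG(tuple(meta["spacing_mm"]))
    )


def assemble_feature_stack(vol: IntensityVolume, config: FilterBankConfig | None = None) -> FeatureStack:
    """Run the full bank on a normalized volume (and its top-hat branch)."""
    config = config or FilterBankConfig()
    maps, names = _branch_maps(vol, config, "raw")
    if config.use_tophat_branch:
        th = white_tophat(vol, config.tophat_radius_mm)
        m2, n2 = _branch_maps(th, config, "tophat")
        maps += m2
        names += n2
    stack = _stack(maps, names, vol.geometry)
    assert stack.n_features == config.feature_count
    return stack
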