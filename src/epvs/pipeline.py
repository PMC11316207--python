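"""Per-subject preprocessing and network-input assembly.

The network consumes 19 co-registered channels per subject: the normalized
T2-weighted image, the 12 PCA feature maps derived from the multi-scale
filter bank, the white-matter mask, and the five regional masks (four
lobes + basal ganglia).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import (
    DEFAULT_N_COMPONENTS,
    FilterBankConfig,
    PCAModel,
    assemble_feature_stack,
    fit_pca,
    transform_pca,
)
from .geometry import VoxelGeometry
from .volume import (
    REGION_LABELS,
    BinaryMask,
    IntensityVolume,
    RegionAtlas,
    denoise,
    robust_z_normalize,
)


@dataclass
class Subject:
    """One hemisphere: image, masks, optional EPVS labels, derived inputs."""

    sid: str
    image: IntensityVolume
    wm: BinaryMask
    atlas: RegionAtlas
    gt_labels: np.ndarray | None = None   # instance-labelled ground truth
    norm: np.ndarray | None = None        # normalized image grid
    inputs: np.ndarray | None = None      # (19, X, Y, Z) float32
    pca: PCAModel | None = None
    _padded: dict = field(default_factory=dict, repr=False)

    @property
    def geometry(self) -> VoxelGeometry:
        return self.image.geometry

    @property
    def gt_mask(self) -> np.ndarray | None:
        return None if self.gt_labels is None else self.gt_labels > 0

    def sampling_mask(self) -> np.ndarray:
        """Voxels eligible as patch centres (white matter by default)."""
        excl = self._padded.get("excluded_region")
        wm = self.wm.grid
        if excl is not None:
            wm = wm & ~excl
        return wm


def assemble_input_channels(
    norm: np.ndarray,
    pca_maps: np.ndarray,
    wm: BinaryMask,
    atlas: RegionAtlas,
) -> np.ndarray:
    """Stack the 19 network input channels in their fixed order."""
    lobar = [(atlas.labels == code).astype(np.float32) for code in REGION_LABELS]
    channels = [norm.astype(np.float32)] + list(pca_maps) + [wm.grid.astype(np.float32)] + lobar
    return np.stack(channels).astype(np.float32)


def prepare_subject(
    sid: str,
    image: IntensityVolume,
    wm: BinaryMask,
    atlas: RegionAtlas,
    gt_labels: np.ndarray | None = None,
    bank: FilterBankConfig | None = None,
    n_components: int = DEFAULT_N_COMPONENTS,
    denoise_method: str = "none",
    denoise_sigma_mm: float = 0.6,
) -> Subject:
    """Normalize, filter, PCA-reduce and assemble one subject's inputs."""
    hemi = atlas.hemisphere_mask()
    normalized = robust_z_normalize(image, hemi)
    normalized = denoise(normalized, denoise_method, denoise_sigma_mm)
    stack = assemble_feature_stack(normalized, bank or FilterBankConfig())
    pca = fit_pca(stack, hemi, n_components)
    pcs = transform_pca(stack, pca)
    inputs = assemble_input_channels(normalized.grid, pcs.maps, wm, atlas)
    return Subject(
        sid=sid,
        image=image,
        wm=wm,
        atlas=atlas,
        gt_labels=gt_labels,
        norm=normalized.grid,
        inputs=inputs,
        pca=pca,
    )


def subject_from_phantom(phantom, sid: str, **kwargs) -> Subject:
    """Prepare a Subject from a synthetic phantom."""
    return prepare_subject(
        sid,
        phantom.image,
        phantom.wm_mask,
        phantom.atlas,
        gt_labels=phantom.gt_labels,
        **kwargs,
    )
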