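"""PCA reduction of the filter bank to the network's feature channels.

The bank's maps are highly correlated across scales and families; a
per-subject PCA over hemisphere-masked voxels reduces them to a small set
of uncorrelated channels (12 by default).  The fit uses a deterministic
solver and a fixed sign convention (the largest-magnitude entry of each
loading is positive) so downstream training is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from ..volume import BinaryMask
from .bank import FeatureStack

DEFAULT_N_COMPONENTS = 12


@dataclass
class PCAModel:
    mean: np.ndarray                     # (n_features,)
    loadings: np.ndarray                 # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray  # (n_components,), non-increasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_features(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_explained_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(stack: FeatureStack, mask: BinaryMask, n_components: int = DEFAULT_N_COMPONENTS) -> PCAModel:
    """Fit PCA on the (masked voxels x features) matrix after centering."""
    if stack.spatial_shape != mask.shape:
        raise ValueError(f"stack shape {stack.spatial_shape} != mask shape {mask.shape}")
    n_vox = mask.n_voxels
    if n_vox <= stack.n_features:
        raise ValueError(
            f"need more masked voxels ({n_vox}) than features ({stack.n_features}) to fit PCA"
        )
    if n_components > stack.n_features:
        raise ValueError(f"n_components={n_components} exceeds feature count {stack.n_features}")

    x = stack.maps[:, mask.grid].T.astype(np.float64)  # (n_vox, n_feat)
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    pca.fit(x)
    if np.any(pca.explained_variance_ <= 1e-12):
        raise ValueError(
            f"input is rank-deficient: fewer than {n_components} components carry variance"
        )
    return PCAModel(
        mean=pca.mean_.copy(),
        loadings=_fix_signs(pca.components_),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def transform_pca(stack: FeatureStack, model: PCAModel, chunk_voxels: int = 1_000_000) -> FeatureStack:
    """Project every voxel of the stack onto the kept components."""
    if stack.n_features != model.n_features:
        raise ValueError(
            f"stack has {stack.n_features} features but the PCA model expects {model.n_features}"
        )
    shape = stack.spatial_shape
    flat = stack.maps.reshape(stack.n_features, -1)
    out = np.empty((model.n_components, flat.shape[1]), dtype=np.float32)
    lt = model.loadings.T.astype(np.float64)
    for start in range(0, flat.shape[1], chunk_voxels):
        sl = slice(start, start + chunk_voxels)
        out[:, sl] = ((flat[:, sl].T.astype(np.float64) - model.mean) @ lt).T
    names = [f"pc-{i + 1:02d}" for i in range(model.n_components)]
    return FeatureStack(out.reshape((model.n_components,) + shape), names, stack.geometry)
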