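"""From a binary EPVS mask to instances, regional counts, densities and bins.

An EPVS instance is a 26-connected component of the segmentation mask
(thin oblique tubes fragment under 6-connectivity on anisotropic grids).
Each instance is assigned to the atlas region holding the majority of its
voxels (ties break to the smallest region code), and per-region counts are
normalized by region volume to densities in counts per cm^3.  Ordinal
binning compresses the right-skewed count distributions: lobar counts are
kept as-is up to the cohort median, the 50th-75th percentile range is split
into three equal intervals, and everything above the 75th percentile forms
one top level; cerebrum totals additionally bin the 0-50th percentile range
into four equal-width levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import VoxelGeometry
from .volume import REGION_LABELS, REGION_NAMES, BinaryMask, RegionAtlas

#: full 26-neighbourhood structuring element
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class EPVSInstance:
    """One connected hyperintense component."""

    instance_id: int
    voxel_indices: np.ndarray  # (n, 3) int array
    volume_mm3: float
    region: int  # atlas code (0 if in unlabeled tissue)
    centroid_mm: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def region_name(self) -> str:
        return REGION_NAMES[self.region]


def label_components(mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Instance-label a binary mask; returns (labels, n)."""
    if connectivity == 26:
        struct = STRUCT_26
    elif connectivity == 6:
        struct = STRUCT_6
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=struct)
    return labels.astype(np.int32), int(n)


def extract_instances(
    mask: BinaryMask | np.ndarray,
    geometry: VoxelGeometry | None = None,
    atlas: RegionAtlas | None = None,
    connectivity: int = 26,
    min_voxels: int = 1,
) -> list[EPVSInstance]:
    """Connected components of the mask as EPVS instances.

    Accepts a :class:`BinaryMask` (geometry taken from it) or a raw binary
    array plus geometry.  An already instance-labelled integer array is
    also accepted, in which case its labels are preserved.
    """
    if isinstance(mask, BinaryMask):
        geometry = mask.geometry
        grid = mask.grid
        labels, n = label_components(grid, connectivity)
    else:
        if geometry is None:
            raise ValueError("geometry is required when passing a raw array")
        arr = np.asarray(mask)
        if arr.dtype != bool and arr.max(initial=0) > 1:
            labels, n = arr.astype(np.int32), int(arr.max())
        else:
            labels, n = label_components(arr.astype(bool), connectivity)
    if atlas is not None and atlas.labels.shape != labels.shape:
        raise ValueError("atlas grid does not match the mask grid")

    vv = geometry.voxel_volume_mm3
    sp = geometry.spacing
    out: list[EPVSInstance] = []
    objs = ndimage.find_objects(labels)
    for lab, sl in enumerate(objs, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        nvox = int(sub.sum())
        if nvox < min_voxels:
            continue
        idx = np.argwhere(sub)
        idx += [s.start for s in sl]
        region = 0
        if atlas is not None:
            codes = atlas.labels[tuple(idx.T)]
            counts = np.bincount(codes, minlength=6)
            region = int(np.argmax(counts))  # argmax ties -> smallest code
        centroid = tuple(float(c) for c in (idx.mean(axis=0) * sp))
        out.append(EPVSInstance(lab, idx, nvox * vv, region, centroid))
    return out


@dataclass
class SubjectEPVSSummary:
    """Per-subject regional EPVS counts and densities."""

    subject_id: str
    counts: dict[str, int]           # per region name
    cerebrum_total: int              # all instances in the hemisphere
    five_region_sum: int
    unassigned: int                  # instances whose majority label is background
    densities_per_cm3: dict[str, float]
    region_volumes_cm3: dict[str, float]

    def as_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id, "cerebrum_total": self.cerebrum_total,
                     "five_region_sum": self.five_region_sum, "unassigned": self.unassigned}
        for name, c in self.counts.items():
            row[f"count_{name}"] = c
        for name, d in self.densities_per_cm3.items():
            row[f"density_{name}_per_cm3"] = d
        return row


def summarize(
    instances: list[EPVSInstance],
    atlas: RegionAtlas,
    geometry: VoxelGeometry | None = None,
    subject_id: str = "",
) -> SubjectEPVSSummary:
    """Regional counts and densities from a set of instances."""
    geometry = geometry or atlas.geometry
    counts = {REGION_NAMES[c]: 0 for c in REGION_LABELS}
    unassigned = 0
    for inst in instances:
        if inst.region == 0:
            unassigned += 1
        else:
            counts[inst.region_name] += 1
    vv_cm3 = geometry.voxel_volume_mm3 / 1000.0
    volumes = {
        REGION_NAMES[c]: float((atlas.labels == c).sum()) * vv_cm3 for c in REGION_LABELS
    }
    densities = {}
    for name, c in counts.items():
        vol = volumes[name]
        densities[name] = (c / vol) if vol > 0 else float("nan")
    return SubjectEPVSSummary(
        subject_id=subject_id,
        counts=counts,
        cerebrum_total=len(instances),
        five_region_sum=sum(counts.values()),
        unassigned=unassigned,
        densities_per_cm3=densities,
        region_volumes_cm3=volumes,
    )


def summaries_to_frame(summaries: list[SubjectEPVSSummary]) -> pd.DataFrame:
    """Subjects x measures table — the input the cohort models consume."""
    return pd.DataFrame([s.as_row() for s in summaries])


# ---------------------------------------------------------------------------
# ordinal binning
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (reproducible across platforms)."""
    v = np.sort(np.asarray(values))
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(q / 100.0 * n))
    return float(v[max(rank, 1) - 1])


@dataclass
class BinningScheme:
    """Monotone mapping from raw EPVS counts to ordinal levels."""

    kind: str                       # 'lobar' or 'cerebrum'
    p50: float
    p75: float
    interval_edges: tuple[float, ...] = field(default_factory=tuple)  # over (p50, p75]
    low_edges: tuple[float, ...] = field(default_factory=tuple)       # cerebrum: over [0, p50]
    collapsed: bool = False

    @property
    def n_levels_above_median(self) -> int:
        return 1 if self.collapsed else 4


def fit_binning(counts, kind: str = "lobar") -> BinningScheme:
    """Fit the percentile binning scheme on a cohort of counts."""
    if kind not in ("lobar", "cerebrum"):
        raise ValueError(f"kind must be 'lobar' or 'cerebrum', got {kind!r}")
    arr = np.asarray(counts)
    if len(arr) < 4:
        raise ValueError("need at least 4 subjects to fit the binning scheme")
    if np.any(arr < 0) or not np.all(arr == np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    p50 = nearest_rank_percentile(arr, 50)
    p75 = nearest_rank_percentile(arr, 75)
    collapsed = p75 <= p50
    if collapsed:
        warnings.warn(
            f"degenerate count spread (p50={p50}, p75={p75}); interval levels collapse",
            stacklevel=2,
        )
        edges: tuple[float, ...] = ()
    else:
        w = (p75 - p50) / 3.0
        edges = (p50, p50 + w, p50 + 2 * w, p75)
    low_edges: tuple[float, ...] = ()
    if kind == "cerebrum":
        if p50 > 0:
            lw = p50 / 4.0
            low_edges = (0.0, lw, 2 * lw, 3 * lw, p50)
        else:
            low_edges = ()
    return BinningScheme(kind=kind, p50=p50, p75=p75, interval_edges=edges,
                         low_edges=low_edges, collapsed=collapsed)


def apply_binning(count: float, scheme: BinningScheme) -> int:
    """Map a raw count to its ordinal level.

    Lobar: identity on [0, p50] ("up to the median"), then levels
    p50+1..p50+3 over the three (left-open, right-closed) intervals of
    (p50, p75], and p50+4 above p75.  Cerebrum: four equal-width levels
    0..3 on [0, p50] (right-closed), then levels 4..6 on the intervals and
    7 above p75 — eight levels in total.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    s = scheme
    if s.kind == "lobar":
        if count <= s.p50:
            return int(count)
        base = int(s.p50)
        if s.collapsed or count > s.p75:
            return base + (1 if s.collapsed else 4)
        w = (s.p75 - s.p50) / 3.0
        k = int(np.ceil((count - s.p50) / w - 1e-12))
        return base + min(max(k, 1), 3)
    # cerebrum
    if count <= s.p50:
        if not s.low_edges:
            return 0
        lw = s.p50 / 4.0
        k = int(np.ceil(count / lw - 1e-12)) if count > 0 else 1
        return min(max(k, 1), 4) - 1
    if s.collapsed or count > s.p75:
        return 4 + (0 if s.collapsed else 3)
    w = (s.p75 - s.p50) / 3.0
    k = int(np.ceil((count - s.p50) / w - 1e-12))
    return 3 + min(max(k, 1), 3)
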