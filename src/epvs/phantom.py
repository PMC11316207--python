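"""Seeded synthetic hemisphere phantoms with ground-truth EPVS.

A phantom emulates an ex vivo T2-weighted hemisphere acquisition at
0.6 x 0.6 x 1.5 mm: a half-ellipsoid "hemisphere" parcellated into four
pseudo-lobes plus a deep basal-ganglia blob, a white-matter compartment
(interior erosion of the hemisphere), and hyperintense curvilinear EPVS
rasterized as tortuous tubes of 0.5-50 mm^3 anchored in white matter.  A
smooth multiplicative bias field and Rician (magnitude-MR) noise complete
the image.  Everything is driven by one ``numpy`` Generator, so phantoms
are bit-identical across runs for a fixed seed.

The generator does not attempt biophysically realistic MR simulation: no
fixation artifacts, no partial-volume model beyond rasterization, uniform
tissue intensity.  Its purpose is ground truth with known instance
bookkeeping for testing segmentation, counting and binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import DEFAULT_SPACING_MM, VoxelGeometry
from .quantify import EPVSInstance, extract_instances
from .volume import BinaryMask, IntensityVolume, RegionAtlas

DEFAULT_REGION_COUNTS = {
    "frontal": 9,
    "parietal": 6,
    "temporal": 2,
    "occipital": 1,
    "basal_ganglia": 4,
}
REGION_CODE = {"frontal": 1, "parietal": 2, "temporal": 3, "occipital": 4, "basal_ganglia": 5}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (96, 96, 48)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    region_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REGION_COUNTS))
    #: instances guaranteed below 3 mm^3 / above 12 mm^3 (counted within region_counts)
    n_small_guaranteed: int = 2
    n_large_guaranteed: int = 4
    radius_range_mm: tuple[float, float] = (0.3, 1.2)
    length_range_mm: tuple[float, float] = (2.0, 15.0)
    tortuosity_deg_per_mm: float = 10.0
    tissue_mean: float = 1.0
    contrast: float = 3.0
    bias_amplitude: float = 0.10
    noise_model: str = "rician"
    noise_sigma: float = 0.1
    n_distractors: int = 3
    wm_erosion_mm: float = 2.4

    def __post_init__(self) -> None:
        if self.contrast <= 1:
            raise ValueError("EPVS contrast must exceed 1 (hyperintense)")
        if self.radius_range_mm[0] < min(self.spacing_mm[:2]) / 2:
            raise ValueError("tube radii below half the in-plane spacing cannot be rasterized")
        if any(c < 0 for c in self.region_counts.values()):
            raise ValueError("region counts must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def total_count(self) -> int:
        return sum(self.region_counts.values())


@dataclass
class Phantom:
    """Synthetic subject: image + atlas + WM mask + ground truth."""

    image: IntensityVolume
    atlas: RegionAtlas
    wm_mask: BinaryMask
    gt_labels: np.ndarray                 # instance-labelled int array
    instances: list[EPVSInstance]
    config: PhantomConfig
    clean_image: IntensityVolume = None   # pre-bias, pre-noise (testing aid)

    @property
    def geometry(self) -> VoxelGeometry:
        return self.image.geometry

    @property
    def gt_mask(self) -> BinaryMask:
        return BinaryMask(self.gt_labels > 0, self.geometry)


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _coords_mm(shape, geometry: VoxelGeometry):
    axes = [np.arange(n) * s for n, s in zip(shape, geometry.spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _build_anatomy(config: PhantomConfig, geometry: VoxelGeometry):
    """Hemisphere mask, atlas and WM mask."""
    shape = config.shape
    xm, ym, zm = _coords_mm(shape, geometry)
    ext = np.asarray(shape) * geometry.spacing
    cx, cy = ext[0] / 2, ext[1] / 2
    # medial (flat) face at z = 0; dome rises in +z
    semi = (0.46 * ext[0], 0.46 * ext[1], 0.92 * ext[2])
    hemi = ((xm - cx) / semi[0]) ** 2 + ((ym - cy) / semi[1]) ** 2 + (zm / semi[2]) ** 2 <= 1.0

    # pseudo-lobes by in-plane quadrant: frontal (+x), parietal (+y),
    # temporal (-x), occipital (-y) half-planes by angle
    ang = np.arctan2(ym - cy, xm - cx)  # broadcast to (X, Y, 1)
    atlas = np.zeros(shape, dtype=np.int16)
    quad = np.select(
        [
            (ang >= -np.pi / 4) & (ang < np.pi / 4),
            (ang >= np.pi / 4) & (ang < 3 * np.pi / 4),
            (ang >= 3 * np.pi / 4) | (ang < -3 * np.pi / 4),
            (ang >= -3 * np.pi / 4) & (ang < -np.pi / 4),
        ],
        [1, 2, 3, 4],
    )
    atlas[...] = np.broadcast_to(quad, shape) * hemi

    # deep basal-ganglia blob near the centre of the flat face
    bg_semi = (0.22 * ext[0], 0.22 * ext[1], 0.30 * ext[2])
    bg = ((xm - cx) / bg_semi[0]) ** 2 + ((ym - cy) / bg_semi[1]) ** 2 + (
        zm / bg_semi[2]
    ) ** 2 <= 1.0
    atlas[bg & hemi] = 5

    dist = ndimage.distance_transform_edt(hemi, sampling=geometry.spacing)
    wm = dist >= config.wm_erosion_mm
    return hemi, RegionAtlas(atlas, geometry), BinaryMask(wm, geometry)


# ---------------------------------------------------------------------------
# tube rasterization
# ---------------------------------------------------------------------------

def _polyline(anchor_mm, length_mm, tortuosity_deg_per_mm, rng, step_mm=0.75):
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [np.asarray(anchor_mm, dtype=float)]
    travelled = 0.0
    while travelled < length_mm:
        step = min(step_mm, length_mm - travelled)
        pts.append(pts[-1] + d * step)
        travelled += step
        # random small rotation of the direction (tortuosity)
        sigma = np.deg2rad(tortuosity_deg_per_mm) * step
        d = d + rng.normal(scale=sigma, size=3)
        d /= np.linalg.norm(d)
    return np.asarray(pts)


def _rasterize_tube(pts_mm, radius_mm, shape, geometry: VoxelGeometry) -> np.ndarray:
    """Boolean mask of voxels within radius of the polyline (physical mm)."""
    sp = geometry.spacing
    lo = np.maximum(np.floor((pts_mm.min(axis=0) - radius_mm) / sp - 1).astype(int), 0)
    hi = np.minimum(np.ceil((pts_mm.max(axis=0) + radius_mm) / sp + 1).astype(int), shape)
    if np.any(hi <= lo):
        return np.zeros(shape, dtype=bool)
    axes = [np.arange(lo[i], hi[i]) * sp[i] for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    vox = np.stack([gx, gy, gz], axis=-1)  # (bx, by, bz, 3)
    mind = np.full(vox.shape[:-1], np.inf)
    for a, b in zip(pts_mm[:-1], pts_mm[1:]):
        ab = b - a
        denom = float(ab @ ab)
        ap = vox - a
        t = np.clip((ap @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + t[..., None] * ab
        d = np.linalg.norm(vox - closest, axis=-1)
        np.minimum(mind, d, out=mind)
    box = mind <= radius_mm
    out = np.zeros(shape, dtype=bool)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = box
    return out


def _sample_tube_params(kind: str, config: PhantomConfig, rng) -> tuple[float, float]:
    """(radius, length) targeting the requested size class."""
    r_lo, r_hi = config.radius_range_mm
    l_lo, l_hi = config.length_range_mm
    if kind == "small":  # < 3 mm^3: thin and short
        return r_lo, float(rng.uniform(l_lo, min(l_lo + 1.0, l_hi)))
    if kind == "large":  # > 12 mm^3: thick and long
        r = float(rng.uniform(max(0.8, r_lo), r_hi))
        return r, float(rng.uniform(max(8.0, l_lo), l_hi))
    return float(rng.uniform(r_lo, r_hi)), float(rng.uniform(l_lo, l_hi))


def make_phantom(config: PhantomConfig | None = None, rng=None) -> Phantom:
    """Generate one phantom; all randomness comes from ``rng``."""
    config = config or PhantomConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    geometry = VoxelGeometry(config.spacing_mm)
    shape = config.shape
    hemi, atlas, wm = _build_anatomy(config, geometry)

    gt = np.zeros(shape, dtype=np.int32)
    next_id = 1
    size_plan: list[tuple[str, str]] = []
    remaining = {k: int(v) for k, v in config.region_counts.items()}
    for kind, budget in (("small", config.n_small_guaranteed), ("large", config.n_large_guaranteed)):
        for _ in range(budget):
            eligible = [r for r, c in remaining.items() if c > 0]
            if not eligible:
                break
            region = eligible[int(np.argmax([remaining[r] for r in eligible]))]
            size_plan.append((region, kind))
            remaining[region] -= 1
    for region, c in remaining.items():
        size_plan.extend([(region, "any")] * c)

    max_tries = max(30, int(len(size_plan) / 0.10))  # 10% retry budget
    for region, kind in size_plan:
        code = REGION_CODE[region]
        anchor_pool = np.argwhere((atlas.labels == code) & wm.grid)
        if len(anchor_pool) == 0:
            raise ValueError(f"region '{region}' has no white-matter anchor voxels")
        placed = False
        vv = geometry.voxel_volume_mm3
        for _ in range(max_tries):
            radius, length = _sample_tube_params(kind, config, rng)
            anchor = anchor_pool[int(rng.integers(len(anchor_pool)))] * geometry.spacing
            pts = _polyline(anchor, length, config.tortuosity_deg_per_mm, rng)
            # clip to the anchor region so regional counts are exact by construction
            tube = _rasterize_tube(pts, radius, shape, geometry) & (atlas.labels == code)
            vol = float(tube.sum()) * vv
            if vol <= 0:
                continue
            if kind == "small" and not vol < 3.0:
                continue
            if kind == "large" and not vol > 12.0:
                continue
            # reject overlap/adjacency with existing instances so counts stay exact
            dil = ndimage.binary_dilation(tube, structure=np.ones((3, 3, 3)))
            if np.any(gt[dil] > 0):
                continue
            gt[tube] = next_id
            next_id += 1
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place the requested EPVS density in region '{region}' "
                "within the retry budget; reduce counts or enlarge the phantom"
            )

    # image: uniform tissue, hyperintense tubes, distractor blobs
    img = np.zeros(shape, dtype=np.float64)
    img[hemi] = config.tissue_mean
    img[gt > 0] = config.tissue_mean * config.contrast
    for _ in range(config.n_distractors):
        pool = np.argwhere(wm.grid & (gt == 0))
        if len(pool) == 0:
            break
        c = pool[int(rng.integers(len(pool)))] * geometry.spacing
        r = rng.uniform(0.8, 1.6)
        xm, ym, zm = _coords_mm(shape, geometry)
        blob = (xm - c[0]) ** 2 + (ym - c[1]) ** 2 + (zm - c[2]) ** 2 <= r**2
        blob &= hemi & (gt == 0)
        img[blob] = config.tissue_mean * (1.0 + 0.5 * (config.contrast - 1.0))
    clean = img.copy()

    if config.bias_amplitude > 0:
        field_ = ndimage.gaussian_filter(rng.normal(size=shape), sigma=12)
        fmax = np.abs(field_).max()
        if fmax > 0:
            field_ = field_ / fmax
        img *= 1.0 + config.bias_amplitude * field_

    if config.noise_sigma > 0:
        if config.noise_model == "gaussian":
            img = img + rng.normal(scale=config.noise_sigma, size=shape)
        else:  # rician magnitude noise
            re = img + rng.normal(scale=config.noise_sigma, size=shape)
            im = rng.normal(scale=config.noise_sigma, size=shape)
            img = np.sqrt(re**2 + im**2)

    image = IntensityVolume(img.astype(np.float32), geometry)
    instances = extract_instances(gt, geometry, atlas=atlas, connectivity=26)
    return Phantom(
        image=image,
        atlas=atlas,
        wm_mask=wm,
        gt_labels=gt,
        instances=instances,
        config=config,
        clean_image=IntensityVolume(clean.astype(np.float32), geometry),
    )


def sample_cohort_config(base: PhantomConfig, rng) -> PhantomConfig:
    """Draw one subject's config: log-normal total count, fixed regional mix.

    The regional mix follows the typical distribution over lobes and basal
    ganglia (frontal-dominant counts, basal ganglia densest); the log-normal
    total gives the right-skewed cohort count distribution the binning
    scheme is designed for.
    """
    mix = {"frontal": 0.45, "parietal": 0.27, "temporal": 0.06, "occipital": 0.02,
           "basal_ganglia": 0.20}
    base_total = max(base.total_count, 1)
    total = int(np.clip(np.rint(rng.lognormal(np.log(base_total), 0.5)), 1, 4 * base_total))
    counts = {k: int(np.floor(total * f)) for k, f in mix.items()}
    short = total - sum(counts.values())
    order = sorted(mix, key=mix.get, reverse=True)
    for i in range(short):
        counts[order[i % len(order)]] += 1
    return replace(base, region_counts=counts)


def make_cohort(
    n_subjects: int,
    config: PhantomConfig | None = None,
    rng=None,
    config_sampler=sample_cohort_config,
) -> list[Phantom]:
    """Generate a cohort with per-subject configs and derived seeds."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    config = config or PhantomConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    phantoms = []
    for _ in range(n_subjects):
        sub_cfg = config_sampler(config, rng) if config_sampler else config
        seed = int(rng.integers(0, 2**31 - 1))
        phantoms.append(make_phantom(sub_cfg, np.random.default_rng(seed)))
    return phantoms
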