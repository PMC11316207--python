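"""Ensemble evaluation protocol: ROIs, detection matching, sensitivity,
Dice overlap and per-ROI voxel-count consistency.

Evaluation regions of interest (ROIs, default 25 x 25 x 9 voxels) are
placed around hyperintense white-matter clusters whose normalized
intensities resemble those of EPVS, balanced across the four lobes and the
basal ganglia.  A ground-truth EPVS counts as detected when the automatic
segmentation overlaps it in at least one voxel; sensitivity is reported
overall and within size bins (volume strictly greater than 0, 3 and
12 mm^3 by default).  Segmentation accuracy is the Dice similarity
coefficient and consistency is the Pearson correlation between manual and
automatic voxel counts per ROI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .quantify import STRUCT_26, label_components
from .volume import REGION_LABELS, REGION_NAMES, BinaryMask

DEFAULT_ROI_SIZE = (25, 25, 9)
DEFAULT_SIZE_THRESHOLDS_MM3 = (0.0, 3.0, 12.0)


@dataclass
class EvalROI:
    subject_id: str
    origin: tuple[int, int, int]     # corner voxel (inclusive)
    size: tuple[int, int, int]
    region: int

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + s) for o, s in zip(self.origin, self.size))

    def contains_any(self, idx: np.ndarray) -> bool:
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.size)
        return bool(np.any(np.all((idx >= lo) & (idx < hi), axis=1)))


@dataclass
class DetectionRecord:
    instance_id: int
    volume_mm3: float
    detected: bool
    roi_id: int
    subject_id: str = ""


@dataclass
class EvalReport:
    sensitivity_overall: float
    sensitivity_by_size: dict[float, float | None]
    dsc: float
    count_correlation: float | None
    n_instances: int
    n_detected: int
    per_roi: pd.DataFrame = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "sensitivity_overall": self.sensitivity_overall,
            "sensitivity_by_size": {str(k): v for k, v in self.sensitivity_by_size.items()},
            "dsc": self.dsc,
            "count_correlation": self.count_correlation,
            "n_instances": self.n_instances,
            "n_detected": self.n_detected,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# ROI generation
# ---------------------------------------------------------------------------

def _roi_candidates(
    norm_grid: np.ndarray,
    wm: np.ndarray,
    region_mask: np.ndarray,
    intensity_percentile: float,
    min_cluster: int = 2,
) -> np.ndarray:
    """Voxels of >=min_cluster hyperintense WM clusters inside a region."""
    wm_vals = norm_grid[wm]
    if wm_vals.size == 0:
        return np.empty((0, 3), dtype=int)
    thr = np.percentile(wm_vals, intensity_percentile)
    hyper = wm & (norm_grid >= thr)
    labels, n = label_components(hyper, connectivity=26)
    if n == 0:
        return np.empty((0, 3), dtype=int)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_cluster
    good = keep[labels] & region_mask
    return np.argwhere(good)


def roi_has_hyperintense_cluster(
    roi: EvalROI,
    norm_grid: np.ndarray,
    wm: np.ndarray,
    intensity_percentile: float = 90.0,
    min_cluster: int = 2,
) -> bool:
    """Independent re-check of the ROI placement condition."""
    wm_vals = norm_grid[wm]
    if wm_vals.size == 0:
        return False
    thr = np.percentile(wm_vals, intensity_percentile)
    sub = (norm_grid >= thr) & wm
    sub = sub[roi.slices]
    labels, n = ndimage.label(sub, structure=STRUCT_26)
    if n == 0:
        return False
    return int(np.bincount(labels.ravel())[1:].max()) >= min_cluster


def generate_rois(
    subjects: list,
    n_per_region: int = 20,
    roi_size: tuple[int, int, int] = DEFAULT_ROI_SIZE,
    intensity_percentile: float = 90.0,
    rng: np.random.Generator | None = None,
    one_per_subject: bool = True,
    max_tries: int = 200,
) -> list[EvalROI]:
    """Randomly place ROIs around hyperintense WM structures.

    ``subjects`` are objects exposing ``sid``, a normalized image grid
    ``norm`` (ndarray), ``wm`` (BinaryMask) and ``atlas`` (RegionAtlas).
    Each ROI must lie fully inside its volume and contain at least one
    hyperintense WM cluster; exactly ``n_per_region`` ROIs are produced per
    region.  With ``one_per_subject`` a subject hosts at most one ROI
    (requires enough subjects); tests on small cohorts can relax it.
    """
    rng = rng or np.random.default_rng()
    size = np.asarray(roi_size)
    rois: list[EvalROI] = []
    used_subjects: set[str] = set()
    for region in REGION_LABELS:
        placed = 0
        tries = 0
        order = rng.permutation(len(subjects))
        while placed < n_per_region:
            tries += 1
            if tries > max_tries * n_per_region:
                raise ValueError(
                    f"could not place {n_per_region} ROIs in region "
                    f"'{REGION_NAMES[region]}': no qualifying hyperintense candidates"
                )
            subj = subjects[int(order[tries % len(subjects)])]
            if one_per_subject and subj.sid in used_subjects:
                continue
            shape = np.asarray(subj.norm.shape)
            if np.any(shape < size):
                continue
            cand = _roi_candidates(
                subj.norm, subj.wm.grid, subj.atlas.labels == region, intensity_percentile
            )
            if len(cand) == 0:
                continue
            center = cand[int(rng.integers(len(cand)))]
            origin = np.clip(center - size // 2, 0, shape - size)
            roi = EvalROI(subj.sid, tuple(int(o) for o in origin), tuple(roi_size), region)
            if not roi_has_hyperintense_cluster(roi, subj.norm, subj.wm.grid, intensity_percentile):
                continue
            rois.append(roi)
            used_subjects.add(subj.sid)
            placed += 1
    return rois


def rois_to_label_map(rois: list[EvalROI], shape: tuple[int, int, int]) -> np.ndarray:
    """ROIs as an integer label volume (1-based, later ROIs overwrite) for
    visual audit; write with :func:`epvs.volume.save_label_map`."""
    out = np.zeros(shape, dtype=np.int32)
    for i, roi in enumerate(rois, start=1):
        out[roi.slices] = i
    return out


# ---------------------------------------------------------------------------
# detection and metrics
# ---------------------------------------------------------------------------

def match_detections(
    gt_labels: np.ndarray,
    pred_mask: BinaryMask | np.ndarray,
    rois: list[EvalROI],
    geometry=None,
    subject_id: str = "",
) -> list[DetectionRecord]:
    """One record per ground-truth instance intersecting any ROI.

    ``gt_labels`` must be instance-labelled (integer ids); a plain binary
    mask is rejected so the caller labels instances explicitly first.
    An instance is detected iff it shares at least one voxel with the
    predicted mask.
    """
    gt = np.asarray(gt_labels)
    if gt.dtype == bool:
        raise ValueError(
            "gt_labels is a plain binary mask; run instance labeling "
            "(quantify.label_components / extract_instances) first"
        )
    if isinstance(pred_mask, BinaryMask):
        geometry = geometry or pred_mask.geometry
        pred = pred_mask.grid
    else:
        pred = np.asarray(pred_mask).astype(bool)
    if geometry is None:
        raise ValueError("geometry required")
    if gt.shape != pred.shape:
        raise ValueError(f"gt shape {gt.shape} != prediction shape {pred.shape}")

    vv = geometry.voxel_volume_mm3
    records: list[DetectionRecord] = []
    objs = ndimage.find_objects(gt)
    for lab, sl in enumerate(objs, start=1):
        if sl is None:
            continue
        inside = gt[sl] == lab
        idx = np.argwhere(inside) + [s.start for s in sl]
        roi_id = next((i for i, roi in enumerate(rois) if roi.contains_any(idx)), None)
        if roi_id is None:
            continue
        detected = bool(np.any(pred[sl][inside]))
        records.append(
            DetectionRecord(lab, float(inside.sum()) * vv, detected, roi_id, subject_id)
        )
    return records


def sensitivity(
    records: list[DetectionRecord],
    size_thresholds_mm3=DEFAULT_SIZE_THRESHOLDS_MM3,
) -> dict[float, float | None]:
    """Detected fraction among instances with volume strictly above each threshold.

    An empty bin yields ``None`` (undefined), not zero.
    """
    out: dict[float, float | None] = {}
    for t in size_thresholds_mm3:
        sub = [r for r in records if r.volume_mm3 > t]
        out[float(t)] = (sum(r.detected for r in sub) / len(sub)) if sub else None
    return out


def dsc_arrays(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|); 1.0 if both empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def dsc(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    ga = a.grid if isinstance(a, BinaryMask) else a
    gb = b.grid if isinstance(b, BinaryMask) else b
    return dsc_arrays(ga, gb)


def dsc_from_confusion(tp: int, fn: int, fp: int) -> float:
    """Dice from confusion counts: 2 TP / (2 TP + FP + FN)."""
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def count_correlation(manual_voxels, auto_voxels) -> float | None:
    """Pearson r between per-ROI manual and automatic voxel counts."""
    m = np.asarray(manual_voxels, dtype=float)
    a = np.asarray(auto_voxels, dtype=float)
    if m.shape != a.shape:
        raise ValueError("paired lists must have equal length")
    if len(m) < 3:
        raise ValueError("need at least 3 paired ROIs")
    if np.std(m) == 0 or np.std(a) == 0:
        return None  # undefined, reported as such
    return float(stats.pearsonr(m, a).statistic)


def evaluate(
    subjects_pred: list[tuple],
    rois: list[EvalROI],
    size_thresholds_mm3=DEFAULT_SIZE_THRESHOLDS_MM3,
) -> EvalReport:
    """Full report over (subject, gt_labels, pred_mask) triples.

    ``subjects_pred`` is a list of (subject_id, gt_labels ndarray,
    pred BinaryMask); ROIs reference subjects by id.  DSC and counts are
    computed within the ROIs only, matching the reading protocol.
    """
    all_records: list[DetectionRecord] = []
    rows = []
    tp = fp = fn = 0
    for sid, gt_labels, pred in subjects_pred:
        subj_rois = [r for r in rois if r.subject_id == sid]
        if not subj_rois:
            continue
        recs = match_detections(gt_labels, pred, subj_rois, subject_id=sid)
        all_records.extend(recs)
        for i, roi in enumerate(subj_rois):
            sl = roi.slices
            g = gt_labels[sl] > 0
            p = pred.grid[sl]
            tp += int((g & p).sum())
            fp += int((~g & p).sum())
            fn += int((g & ~p).sum())
            rows.append(
                {
                    "subject_id": sid,
                    "region": REGION_NAMES[roi.region],
                    "origin": roi.origin,
                    "manual_voxels": int(g.sum()),
                    "auto_voxels": int(p.sum()),
                    "n_instances": sum(r.roi_id == i for r in recs),
                    "n_detected": sum(r.roi_id == i and r.detected for r in recs),
                }
            )
    per_roi = pd.DataFrame(rows)
    sens = sensitivity(all_records, size_thresholds_mm3)
    corr = None
    if len(per_roi) >= 3:
        corr = count_correlation(per_roi["manual_voxels"], per_roi["auto_voxels"])
    return EvalReport(
        sensitivity_overall=sens[min(sens)] if sens else None,
        sensitivity_by_size=sens,
        dsc=dsc_from_confusion(tp, fn, fp),
        count_correlation=corr,
        n_instances=len(all_records),
        n_detected=sum(r.detected for r in all_records),
        per_roi=per_roi,
    )
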