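"""Desk-scale end-to-end study on synthetic phantoms.

Runs the full pipeline at CPU scale: generate a small labelled cohort,
extract features, train a leave-one-out ensemble, and score the ensemble
on a freshly generated phantom the training never saw — held-out Dice,
size-binned detection rates and per-ROI voxel-count consistency.  Problem
sizes (4 subjects of 48 x 48 x 24 voxels, reduced filter bank, 8-channel
network, 16 x 16 x 8 patches) are the package's desk-scale defaults; see
docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .evaluation import dsc_arrays, evaluate, generate_rois
from .features import FilterBankConfig
from .phantom import PhantomConfig, make_cohort, make_phantom
from .pipeline import subject_from_phantom
from .training import desk_scale_configs, predict_ensemble, train_ensemble_loocv
from .volume import BinaryMask

DESK_BANK = FilterBankConfig(
    sf_sigmas_mm=(0.5, 1.0),
    ff_sigmas_mm=(0.6, 1.0, 1.8),
    oof_radii_mm=(0.6, 1.0, 1.8),
)
DESK_PHANTOM = PhantomConfig(shape=(48, 48, 24))


def run_desk_scale_study(
    seed: int,
    n_subjects: int = 4,
    phantom_config: PhantomConfig = DESK_PHANTOM,
    bank: FilterBankConfig = DESK_BANK,
) -> dict:
    """Train a reduced LOOCV ensemble and score it on a fresh phantom."""
    rng = np.random.default_rng(seed)
    cohort = make_cohort(n_subjects, phantom_config, rng, config_sampler=None)
    subjects = [
        subject_from_phantom(p, f"s{i:02d}", bank=bank) for i, p in enumerate(cohort)
    ]
    fresh = make_phantom(phantom_config, np.random.default_rng(seed + 500))
    fresh_subject = subject_from_phantom(fresh, "fresh", bank=bank)

    net_config, train_config = desk_scale_configs()
    train_config.seed = seed
    ensemble = train_ensemble_loocv(subjects, net_config, train_config)

    prob, mask = predict_ensemble(ensemble, fresh_subject)
    whole_dsc = dsc_arrays(mask, fresh.gt_labels > 0)

    rates: dict[float, float | None] = {}
    for threshold_mm3 in (0.0, 3.0, 12.0):
        insts = [i for i in fresh.instances if i.volume_mm3 > threshold_mm3]
        if insts:
            hit = sum(bool(mask[tuple(i.voxel_indices.T)].any()) for i in insts)
            rates[threshold_mm3] = hit / len(insts)
        else:
            rates[threshold_mm3] = None

    rois = generate_rois(
        [fresh_subject],
        n_per_region=2,
        roi_size=(25, 25, 9),
        rng=np.random.default_rng(seed + 900),
        one_per_subject=False,
    )
    report = evaluate(
        [("fresh", fresh.gt_labels, BinaryMask(mask, fresh.geometry))], rois
    )
    return {
        "seed": seed,
        "n_subjects": n_subjects,
        "n_voxels": int(np.prod(phantom_config.shape)),
        "member_validation_dsc": [m.best_validation_dsc for m in ensemble.members],
        "heldout_dsc": whole_dsc,
        "detection_rate_overall": rates[0.0],
        "detection_rate_over_3mm3": rates[3.0],
        "detection_rate_over_12mm3": rates[12.0],
        "roi_dsc": report.dsc,
        "roi_count_correlation": report.count_correlation,
        "n_gt_instances": len(fresh.instances),
    }
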