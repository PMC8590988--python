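"""Reproduction workflows: the package's benchmark experiments.

Desk-scale analogs of the clinical evaluation, run entirely on seeded
synthetic phantoms:

- :func:`detection_experiment` — train the dual-view localizer on 120
  phantoms (30% truncated) and evaluate existence accuracy and mean
  3-D box IOU on 40 held-out phantoms.
- :func:`independent_cohort_accuracy` — existence accuracy on a fresh
  24-phantom cohort, all containing the whole brain.
- :func:`lesion_detection_experiment` — 4 lesioned subjects against 20
  controls through the full extract -> normalize -> smooth -> t-map
  pipeline at uncorrected P < 0.001.

All randomness is derived from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model as model_mod
from . import phantom, pipeline, statmap

COHORT_N = 160
TRAIN_N = 120
TRUNCATED_FRACTION = 0.3
INDEPENDENT_N = 24
N_CONTROLS = 20
N_SUBJECTS = 4
LESION = phantom.LesionSpec((0, 0, 0), radius_mm=12.0, multiplier=0.5)


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


@dataclass
class DetectionResult:
    model: model_mod.DualViewModel
    accuracy_pct: float
    iou_mean_pct: float
    iou_sd_pct: float
    n_test: int


def detection_experiment(seed: int = 1, epochs: int = 120) -> DetectionResult:
    """Train on 120 seeded phantoms, evaluate on 40 held out."""
    s_cohort, s_split, s_train = _subseeds(seed, 3)
    cohort = phantom.generate_cohort(
        COHORT_N, phantom.CohortSpec(truncated_fraction=TRUNCATED_FRACTION),
        seed=s_cohort,
    )
    dataset = model_mod.make_dataset(cohort)
    order = np.random.default_rng(s_split).permutation(COHORT_N)
    train_ds = [dataset[i] for i in order[:TRAIN_N]]
    test_ds = [dataset[i] for i in order[TRAIN_N:]]
    trained, _ = model_mod.train(
        train_ds, model_mod.ModelConfig.small(),
        model_mod.TrainConfig.desk_scale(seed=s_train, epochs=epochs),
    )
    ev = model_mod.evaluate(trained, test_ds)
    return DetectionResult(
        model=trained,
        accuracy_pct=100.0 * ev["accuracy"],
        iou_mean_pct=100.0 * ev["iou_mean"],
        iou_sd_pct=100.0 * ev["iou_sd"],
        n_test=len(test_ds),
    )


def independent_cohort_accuracy(trained: model_mod.DualViewModel,
                                seed: int = 1) -> tuple[float, int]:
    """Existence accuracy (%) on a fresh all-whole-brain 24-phantom cohort."""
    (s_cohort,) = _subseeds(seed + 1_000_003, 1)
    cohort = phantom.generate_cohort(
        INDEPENDENT_N, phantom.CohortSpec(truncated_fraction=0.0), seed=s_cohort
    )
    dataset = model_mod.make_dataset(cohort)
    ev = model_mod.evaluate(trained, dataset)
    return 100.0 * ev["accuracy"], INDEPENDENT_N


def lesion_detection_experiment(trained: model_mod.DualViewModel | None,
                                seed: int = 1) -> dict:
    """4 lesioned subjects vs 20 controls through the full pipeline.

    ``trained=None`` substitutes ground-truth boxes for the extraction
    step (used to isolate the statistical stage in testing); normally
    the trained model drives extraction for every scan.
    """
    s_template, s_controls, s_subjects = _subseeds(seed + 2_000_003, 3)
    template = phantom.make_template(20, seed=s_template)

    controls = phantom.generate_cohort(
        N_CONTROLS, phantom.CohortSpec(truncated_fraction=0.0), seed=s_controls
    )
    normalized = []
    for vol, truth in controls:
        box = None if trained is not None else truth.brain_box
        scan = pipeline.process_scan(vol, trained, template, box=box)
        if isinstance(scan, pipeline.AbsentBrain):
            continue
        normalized.append(scan.smoothed)

    subjects = phantom.generate_cohort(
        N_SUBJECTS,
        phantom.CohortSpec(truncated_fraction=0.0, lesion=LESION),
        seed=s_subjects,
    )
    hits, peaks = 0, []
    for vol, truth in subjects:
        box = None if trained is not None else truth.brain_box
        res = pipeline.analyze_subject(vol, normalized, trained, template, box=box)
        if isinstance(res, pipeline.AbsentBrain):
            peaks.append(np.nan)
            continue
        scan, tmap, report = res
        lesion_t = pipeline.warp_mask_to_template(truth.lesion_mask, vol, scan,
                                                  template)
        if statmap.detect_lesion(report, lesion_t):
            hits += 1
        peaks.append(report.clusters[0].peak_t if report.clusters else np.nan)
    return {
        "hits": hits,
        "n_subjects": N_SUBJECTS,
        "n_controls": len(normalized),
        "peak_t": peaks,
    }
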