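"""Reference phantom experiments at desk scale.

These presets define the canonical CPU-scale study the test-suite and the
reproduction script both run: a tiny cascade detector trained on windows
mined from 150 phantoms and scored on 200 held-out phantoms, a tiny Siamese
grader trained on 1000 phantoms (200 validation) and scored on 300 held-out
phantoms, and the full simulate -> preprocess -> detect -> crop -> predict ->
evaluate closure on 50 double-knee frames. All randomness derives from one
integer seed; disjoint sub-seeds keep training and evaluation sets separate.
"""

from __future__ import annotations

import numpy as np

from .detector import (CascadeConfig, DetectorTrainConfig, Stage1Net,
                       Stage2Net, detect, detection_accuracy,
                       tiny_cascade_config, train_detector)
from .grader import SiameseGrader, TASKS, predict_pairs, tiny_grader_config
from .metrics import evaluate_report
from .pipeline import grading_arrays, run_end_to_end, standardize_sample
from .synth import compose_double, generate_samples
from .trainer import tiny_train_config, train_grader

DETECTOR_N_TRAIN = 150
DETECTOR_N_TEST = 200
GRADER_N_TRAIN = 1000
GRADER_N_VAL = 200
GRADER_N_TEST = 300
E2E_N_DOUBLE = 50
PATCH_SIZE = 64


def _sub(seed: int, k: int) -> int:
    return (seed * 1000 + k) % (2 ** 31 - 1)


def train_tiny_detector(seed: int, n_train: int = DETECTOR_N_TRAIN,
                        log: list | None = None
                        ) -> tuple[Stage1Net, Stage2Net, CascadeConfig]:
    """Train the tiny cascade on standardized phantoms."""
    config = tiny_cascade_config()
    train = [standardize_sample(s)
             for s in generate_samples(n_train, seed=_sub(seed, 1))]
    tcfg = DetectorTrainConfig(epochs=10, lr_stage1=1e-3, lr_stage2=1e-3,
                               batch_size=64, seed=_sub(seed, 2))
    stage1, stage2 = train_detector(train, config, tcfg, log=log)
    return stage1, stage2, config


def eval_tiny_detector(stage1: Stage1Net, stage2: Stage2Net,
                       config: CascadeConfig, seed: int,
                       n_test: int = DETECTOR_N_TEST) -> dict:
    """Detection accuracy (IoU >= 0.5) on held-out standardized phantoms."""
    test = [standardize_sample(s)
            for s in generate_samples(n_test, seed=_sub(seed, 3))]
    dets = [detect(s.image, stage1, stage2, config) for s in test]
    truth = [s.box for s in test]
    return {
        "accuracy": detection_accuracy(dets, truth, iou_min=config.iou_min),
        "n": n_test,
        "n_missed": sum(d is None for d in dets),
    }


def train_tiny_grader(seed: int, n_train: int = GRADER_N_TRAIN,
                      n_val: int = GRADER_N_VAL
                      ) -> tuple[SiameseGrader, list[dict]]:
    """Train the tiny Siamese grader on ground-truth-cropped patch pairs."""
    cfg = tiny_grader_config(patch_size=PATCH_SIZE)
    data = {
        "train": grading_arrays(generate_samples(n_train, seed=_sub(seed, 4)),
                                cfg.patch_size),
        "val": grading_arrays(generate_samples(n_val, seed=_sub(seed, 5)),
                              cfg.patch_size),
    }
    model = SiameseGrader(cfg, seed=_sub(seed, 6))
    log = train_grader(data, model, tiny_train_config(seed=_sub(seed, 7)))
    return model, log


def eval_tiny_grader(model: SiameseGrader, seed: int,
                     n_test: int = GRADER_N_TEST) -> dict:
    """Per-task top1/top±1/kappa/MSE on held-out phantoms."""
    test = grading_arrays(generate_samples(n_test, seed=_sub(seed, 8)),
                          model.config.patch_size)
    preds = predict_pairs(model, test["left"], test["right"])
    pred_arrays = {t: np.array([p.grades[t] for p in preds]) for t, _ in TASKS}
    report = evaluate_report(pred_arrays, test["labels"])
    return report


def run_e2e_study(stage1, stage2, cascade, grader, seed: int,
                  n_double: int = E2E_N_DOUBLE, polarity_mix: float = 0.3) -> dict:
    """Full-pipeline closure on double-knee frames with mixed polarity."""
    singles = generate_samples(2 * n_double, seed=_sub(seed, 9),
                               polarity_mix=polarity_mix)
    doubles = [compose_double(singles[2 * i], singles[2 * i + 1])
               for i in range(n_double)]
    return run_end_to_end(doubles, stage1, stage2, cascade, grader,
                          patch_size=grader.config.patch_size)
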