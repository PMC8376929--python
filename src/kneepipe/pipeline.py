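"""Shared orchestration: dataset assembly and the end-to-end pipeline.

Glue between the stages: standardizing phantom samples the way real inputs
are standardized, turning labeled samples into grading tensors (via ground
truth during grader training, via the trained detector at inference), model
checkpointing for the detector pair, and the simulate -> preprocess ->
detect -> crop -> predict -> evaluate closure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .detector import (CascadeConfig, Detection, Stage1Net, Stage2Net, detect)
from .grader import TASKS, GradePrediction, SiameseGrader, predict_pairs
from .image import KneeImage
from .metrics import evaluate_report
from .preprocess import normalize_polarity, split_double_knee, standardize_intensity
from .roi import refine_roi, split_patches
from .synth import PhantomSample


def load_dataset(path: str | Path) -> tuple[list[PhantomSample], "object"]:
    """Read a simulated dataset directory (labels.csv, keypoints.json, PNGs)
    back into :class:`PhantomSample` objects. Returns (samples, manifest)."""
    import pandas as pd

    from .image import read_image

    path = Path(path)
    df = pd.read_csv(path / "labels.csv")
    with open(path / "keypoints.json") as fh:
        kp = json.load(fh)
    samples = []
    for _, row in df.iterrows():
        rec = kp[row["knee_id"]]
        img = read_image(path / rec["image"], side="left")
        img.polarity = "dark_background"
        labels = {t: int(row[t]) for t, _ in TASKS}
        samples.append(PhantomSample(
            image=img, box=np.array(rec["box"], dtype=np.float64),
            keypoints=np.array(rec["keypoints"], dtype=np.float64),
            labels=labels, spec=None))
    return samples, df


def standardize_sample(sample: PhantomSample) -> PhantomSample:
    """Apply the preprocessing stack to a phantom; geometry is unchanged."""
    img = standardize_intensity(normalize_polarity(sample.image))
    return PhantomSample(image=img, box=sample.box, keypoints=sample.keypoints,
                         labels=sample.labels, spec=sample.spec)


def labels_arrays(samples: list[PhantomSample]) -> dict[str, np.ndarray]:
    return {t: np.array([s.labels[t] for s in samples], dtype=np.int64)
            for t, _ in TASKS}


def grading_arrays(samples: list[PhantomSample], patch_size: int,
                   margin_factor: float = 0.2,
                   standardize: bool = True) -> dict:
    """Ground-truth-driven grading tensors: left/right patch stacks, whole-ROI
    stack and the eight-task label arrays."""
    lefts, rights, rois = [], [], []
    for s in samples:
        if standardize:
            s = standardize_sample(s)
        det = Detection(box=s.box, score=1.0, keypoints=s.keypoints)
        box = refine_roi(det, image_shape=s.image.shape,
                         margin_factor=margin_factor)
        pair = split_patches(s.image, box, patch_size=patch_size)
        lefts.append(pair.left_patch)
        rights.append(pair.right_patch_flipped)
        x1, y1, x2, y2 = (int(v) for v in pair.origin_box)
        roi = s.image.pixels[y1:y2, x1:x2].astype(np.float64) / 255.0
        rois.append(resize(roi, (patch_size, patch_size), order=1,
                           anti_aliasing=False))
    return {"left": np.stack(lefts), "right": np.stack(rights),
            "roi": np.stack(rois), "labels": labels_arrays(samples)}


def split_samples(samples: list[PhantomSample], seed: int,
                  ratios: tuple[int, int, int] = (5, 1, 3)) -> dict[str, list]:
    """Stratified (by KL) train/val/test partition with the given ratios."""
    from .synth import assign_splits

    kl = np.array([s.labels["kl"] for s in samples])
    split = assign_splits(kl, seed, ratios)
    return {name: [s for s, tag in zip(samples, split) if tag == name]
            for name in ("train", "val", "test")}


# ---------------------------------------------------------------------------
# detector checkpoints


def save_detector(stage1: Stage1Net, stage2: Stage2Net, config: CascadeConfig,
                  path: str | Path) -> None:
    arrays = {f"s1_{k}": v for k, v in stage1.state_dict().items()}
    arrays.update({f"s2_{k}": v for k, v in stage2.state_dict().items()})
    np.savez(Path(path), __config__=json.dumps(config.__dict__), **arrays)


def load_detector(path: str | Path) -> tuple[Stage1Net, Stage2Net, CascadeConfig]:
    data = np.load(Path(path), allow_pickle=False)
    raw = json.loads(str(data["__config__"]))
    config = CascadeConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in raw.items()})
    rng = np.random.default_rng(0)
    stage1, stage2 = Stage1Net(config, rng), Stage2Net(config, rng)
    stage1.load_state_dict({k[3:]: data[k] for k in data.files if k.startswith("s1_")})
    stage2.load_state_dict({k[3:]: data[k] for k in data.files if k.startswith("s2_")})
    return stage1, stage2, config


# ---------------------------------------------------------------------------
# end-to-end closure


def run_end_to_end(doubles: list[tuple[KneeImage, list[PhantomSample]]],
                   stage1: Stage1Net, stage2: Stage2Net, cascade: CascadeConfig,
                   grader: SiameseGrader, patch_size: int,
                   margin_factor: float = 0.2,
                   kappa_weighting: str = "quadratic") -> dict:
    """Full pipeline on double-knee frames with per-knee ground-truth labels.

    Preprocesses each frame, detects each knee, refines the ROI from the six
    detected key points, splits/flips patches, grades them, and evaluates
    against the truth labels. Knees with no surviving detection are counted
    in ``n_missed`` and excluded from grading metrics.
    """
    lefts, rights, kept_labels, detections, truths = [], [], [], [], []
    n_missed = 0
    for frame, knee_truths in doubles:
        frame = normalize_polarity(frame)
        halves = split_double_knee(frame)
        for half, truth in zip(halves, knee_truths):
            std = standardize_intensity(half)
            offset = 0.0 if half.side == "left" else frame.shape[1] // 2
            det = detect(std, stage1, stage2, cascade)
            local_box = truth.box - np.array([offset, 0, offset, 0])
            detections.append(det)
            truths.append(local_box)
            if det is None:
                n_missed += 1
                continue
            box = refine_roi(det, image_shape=std.shape,
                             margin_factor=margin_factor)
            pair = split_patches(std, box, patch_size=patch_size)
            lefts.append(pair.left_patch)
            rights.append(pair.right_patch_flipped)
            kept_labels.append(truth.labels)

    preds: list[GradePrediction] = []
    if lefts:
        preds = predict_pairs(grader, np.stack(lefts), np.stack(rights))
    pred_arrays = {t: np.array([p.grades[t] for p in preds]) for t, _ in TASKS}
    label_arrays = {t: np.array([lab[t] for lab in kept_labels])
                    for t, _ in TASKS}
    report = (evaluate_report(pred_arrays, label_arrays, kappa_weighting)
              if preds else {"n_samples": 0, "tasks": {}})
    report["n_missed"] = n_missed
    report["n_knees"] = len(detections)
    return {"report": report, "detections": detections, "truth_boxes": truths,
            "predictions": preds, "labels": kept_labels}
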