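"""Two-level cascaded multi-task knee-joint detector.

Stage 1 is a small fully convolutional network scanned over an image pyramid;
for every sliding-window position it scores knee/non-knee and regresses a
normalized 4-vector of bounding-box offsets. Stage 2 re-scores the surviving
candidates at higher resolution and additionally regresses the 12-vector of
six joint-margin key points. Both stages are trained with the weighted
multi-task objective

    L = a_det * CE(knee) + a_box * Euclidean(box) + a_kp * Euclidean(keypoints)

with stage-specific weights (stage 1: 1, 0.5, 0 — no key points; stage 2:
0.8, 0.6, 1.5). Inference runs pyramid -> stage-1 threshold -> offset
refinement -> NMS -> stage-2 -> threshold -> refinement -> NMS and keeps the
single best detection (one knee per single-knee image).

Box convention: 0-based pixel coordinates, half-open [min, max). Regression
targets are (truth - window) / window_side for the four box coordinates and
(keypoint - window_origin) / window_side for key points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .image import KneeImage
from .nn.losses import bce_with_logits, mse_loss, sigmoid
from .synth import PhantomSample, crop_window, sample_detector_windows


class PyramidError(ValueError):
    """Image too small to build a non-empty detection pyramid."""


@dataclass
class Detection:
    box: np.ndarray                      # [x1, y1, x2, y2]
    score: float
    keypoints: np.ndarray | None = None  # (6, 2)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class CascadeConfig:
    stage1_input_size: int = 48
    stage2_input_size: int = 96
    pyramid_scale_factor: float = 0.709
    min_knee_size: int = 80
    stage1_score_threshold: float = 0.6
    stage2_score_threshold: float = 0.7
    nms_iou_stage1: float = 0.7
    nms_iou_stage2: float = 0.5
    stage1_alphas: tuple[float, float, float] = (1.0, 0.5, 0.0)
    stage2_alphas: tuple[float, float, float] = (0.8, 0.6, 1.5)
    stage1_channels: tuple[int, int, int] = (16, 32, 64)
    stage2_channels: tuple[int, int, int, int] = (32, 64, 64, 128)
    stage2_fc_units: int = 256
    iou_min: float = 0.5                 # what counts as a correct detection

    def __post_init__(self):
        if not 0 < self.pyramid_scale_factor < 1:
            raise ValueError("pyramid_scale_factor must be in (0, 1)")
        for t in (self.stage1_score_threshold, self.stage2_score_threshold,
                  self.nms_iou_stage1, self.nms_iou_stage2):
            if not 0 < t < 1:
                raise ValueError("thresholds must be in (0, 1)")
        if any(a < 0 for a in self.stage1_alphas + self.stage2_alphas):
            raise ValueError("loss weights must be non-negative")
        if self.stage1_input_size % 8:
            raise ValueError("stage1_input_size must be divisible by 8 (three pools)")


def tiny_cascade_config() -> CascadeConfig:
    """Desk-scale profile: smaller windows and channel widths for CPU runs."""
    return CascadeConfig(stage1_input_size=24, stage2_input_size=48,
                         stage1_channels=(8, 16, 24),
                         stage2_channels=(16, 24, 32, 48), stage2_fc_units=96)


# ---------------------------------------------------------------------------
# geometry


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two [x1,y1,x2,y2] boxes (half-open)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0.0, ix2 - ix1) * max(0.0, iy2 - iy1)
    if inter == 0.0:
        return 0.0
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return float(inter / union)


def nms(detections: list[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression; ties broken by earlier input index.

    Keeps the highest-scoring detection, drops every remaining detection whose
    IoU with a kept box exceeds ``iou_threshold``, repeats. Output is sorted
    by score descending.
    """
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, i))
    kept: list[int] = []
    for i in order:
        if all(iou(detections[i].box, detections[j].box) <= iou_threshold
               for j in kept):
            kept.append(i)
    return [detections[i] for i in kept]


def to_square(box: np.ndarray) -> np.ndarray:
    """Expand a box to a square about its center (longest side)."""
    w, h = box[2] - box[0], box[3] - box[1]
    side = max(w, h)
    cx, cy = (box[0] + box[2]) / 2.0, (box[1] + box[3]) / 2.0
    return np.array([cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2])


def build_pyramid(pixels: np.ndarray, config: CascadeConfig
                  ) -> list[tuple[float, np.ndarray]]:
    """Scale list s_k = (input/min_knee) * factor^k while the resized smaller
    side still admits one stage-1 window. Returns (scale, resized) pairs with
    strictly decreasing sizes; pixels are float in [0, 1]."""
    from skimage.transform import resize

    h, w = pixels.shape
    if min(h, w) < config.min_knee_size:
        raise PyramidError(
            f"image {h}x{w} smaller than min_knee_size {config.min_knee_size}")
    base = pixels.astype(np.float64) / 255.0 if pixels.dtype == np.uint8 else pixels
    out = []
    scale = config.stage1_input_size / config.min_knee_size
    while min(h, w) * scale >= config.stage1_input_size:
        nh, nw = int(round(h * scale)), int(round(w * scale))
        out.append((scale, resize(base, (nh, nw), order=1, anti_aliasing=False)))
        scale *= config.pyramid_scale_factor
    if not out:
        raise PyramidError("empty pyramid")
    return out


# ---------------------------------------------------------------------------
# networks


class Stage1Net(nn.Module):
    """Fully convolutional stage-1 network.

    Three (valid conv, maxpool) stages, then three convolutions (a 3x3, a
    final spatial-collapse layer, and the 1x1 output head producing 5
    channels: knee logit + 4 box offsets). All convolutions are unpadded so
    sliding-window outputs are exactly the per-crop outputs of the
    corresponding ``input_size`` windows at stride-8 positions. Applied to an
    ``input_size`` square the output grid is 1x1.
    """

    STRIDE = 8

    def __init__(self, config: CascadeConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3 = config.stage1_channels
        self.input_size = i = config.stage1_input_size
        # spatial size after three (3x3 valid conv, pool2) stages
        s3 = ((((i - 2) // 2 - 2) // 2 - 2) // 2)
        if s3 < 1:
            raise ValueError("stage1_input_size too small for three conv+pool stages")
        k4 = 3 if s3 >= 3 else s3           # penultimate conv kernel
        k5 = s3 - k4 + 1                     # collapses the window to 1x1
        self.net = nn.Sequential(
            nn.Conv2d(1, c1, 3, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c1, c2, 3, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c2, c3, 3, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c3, c3, k4, rng=rng), nn.ReLU(),
            nn.Conv2d(c3, 2 * c3, k5, rng=rng), nn.ReLU(),
            nn.Conv2d(2 * c3, 5, 1, rng=rng),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N,1,H,W) -> (N,5,Hg,Wg) map of [logit, dx1, dy1, dx2, dy2]."""
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


class Stage2Net(nn.Module):
    """Stage-2 refinement network on fixed-size crops.

    Three (conv, maxpool) stages, one valid convolution, then two FC layers
    fanning out into the three heads: knee logit (1), box offsets (4), key
    points (12).
    """

    def __init__(self, config: CascadeConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3, c4 = config.stage2_channels
        self.input_size = config.stage2_input_size
        s = config.stage2_input_size // 8
        if s < 3:
            raise ValueError("stage2_input_size too small")
        self.trunk = nn.Sequential(
            nn.Conv2d(1, c1, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c1, c2, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c2, c3, 3, padding=1, rng=rng), nn.ReLU(), nn.MaxPool2d(2),
            nn.Conv2d(c3, c4, 3, rng=rng), nn.ReLU(),
            nn.Flatten(),
            nn.Linear(c4 * (s - 2) * (s - 2), config.stage2_fc_units, rng=rng),
            nn.ReLU(),
        )
        self.head_score = nn.Linear(config.stage2_fc_units, 1, rng=rng)
        self.head_box = nn.Linear(config.stage2_fc_units, 4, rng=rng)
        self.head_kp = nn.Linear(config.stage2_fc_units, 12, rng=rng)

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        n, _, h, w = x.shape
        if (h, w) != (self.input_size, self.input_size):
            raise ValueError(f"stage-2 expects {self.input_size}px crops, got {h}x{w}")
        f = self.trunk.forward(x)
        return {
            "logit": self.head_score.forward(f)[:, 0],
            "box": self.head_box.forward(f),
            "kp": self.head_kp.forward(f),
        }

    def backward(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        df = self.head_score.backward(grads["logit"][:, None])
        df = df + self.head_box.backward(grads["box"])
        df = df + self.head_kp.backward(grads["kp"])
        return self.trunk.backward(df)


# ---------------------------------------------------------------------------
# loss


def multitask_loss(pred: dict[str, np.ndarray], target: dict[str, np.ndarray],
                   alpha_det: float, alpha_box: float, alpha_kp: float,
                   return_grads: bool = False):
    """Weighted multi-task detection loss, averaged over the batch.

    ``pred``: ``logit`` (N,), ``box`` (N,4), optionally ``kp`` (N,12).
    ``target``: ``label`` (N,) in {1 knee, 0 non-knee, -1 part}, ``box`` (N,4),
    optionally ``kp`` (N,12). Part samples contribute only the box term;
    negatives contribute only the classification term.
    """
    if min(alpha_det, alpha_box, alpha_kp) < 0:
        raise ValueError("loss weights must be non-negative")
    labels = np.asarray(target["label"])
    cls_mask = labels >= 0
    pos_mask = labels == 1
    box_mask = labels != 0

    grads = {k: np.zeros_like(v) for k, v in pred.items()}
    total = 0.0
    if cls_mask.any() and alpha_det > 0:
        l, d = bce_with_logits(pred["logit"][cls_mask],
                               labels[cls_mask].astype(np.float64))
        total += alpha_det * l
        grads["logit"][cls_mask] = alpha_det * d
    if alpha_box > 0 and box_mask.any():
        l, d = mse_loss(pred["box"], target["box"], mask=box_mask)
        total += alpha_box * l
        grads["box"] = alpha_box * d
    if alpha_kp > 0 and "kp" in pred and pos_mask.any():
        l, d = mse_loss(pred["kp"], target["kp"], mask=pos_mask)
        total += alpha_kp * l
        grads["kp"] = alpha_kp * d
    if return_grads:
        return total, grads
    return total


# ---------------------------------------------------------------------------
# inference


def _normalize(x: np.ndarray) -> np.ndarray:
    return x - 0.5


def detect(img: KneeImage | np.ndarray, stage1: Stage1Net, stage2: Stage2Net,
           config: CascadeConfig, return_all: bool = False):
    """Full cascade inference on one standardized single-knee image.

    Returns the highest-scoring :class:`Detection` with key points mapped back
    to original image coordinates, or ``None`` when nothing survives both
    stages. ``return_all=True`` returns every stage-2 survivor (post NMS).
    """
    pixels = img.pixels if isinstance(img, KneeImage) else img
    stage2.eval()
    cands = nms(_stage1_candidates(pixels, stage1, config), config.nms_iou_stage1)
    if not cands:
        return [] if return_all else None

    squares = [to_square(c.box) for c in cands]
    crops = np.stack([crop_window(pixels, sq, config.stage2_input_size)
                      for sq in squares])
    out = stage2.forward(_normalize(crops[:, None]))
    scores = sigmoid(out["logit"])
    final: list[Detection] = []
    h, w = pixels.shape
    for k, sq in enumerate(squares):
        if scores[k] < config.stage2_score_threshold:
            continue
        side = sq[2] - sq[0]
        box = sq + out["box"][k] * side
        box = np.clip(box, [0, 0, 0, 0], [w, h, w, h])
        if box[2] <= box[0] or box[3] <= box[1]:
            continue
        kp = sq[:2] + out["kp"][k].reshape(6, 2) * side
        final.append(Detection(box, float(scores[k]), kp))
    final = nms(final, config.nms_iou_stage2)
    if return_all:
        return final
    return final[0] if final else None


def detection_accuracy(detections: list[Detection | None],
                       truth_boxes: list[np.ndarray],
                       iou_min: float = 0.5) -> float:
    """Fraction of images with a detection of IoU >= ``iou_min`` vs truth."""
    if len(detections) != len(truth_boxes):
        raise ValueError("detections and truths must pair up")
    if not detections:
        raise ValueError("empty evaluation set")
    hits = sum(1 for d, t in zip(detections, truth_boxes)
               if d is not None and iou(d.box, t) >= iou_min)
    return hits / len(detections)


# ---------------------------------------------------------------------------
# training


@dataclass
class DetectorTrainConfig:
    epochs: int = 10
    lr_stage1: float = 1e-3
    lr_stage2: float = 1e-4
    batch_size: int = 500
    weight_decay: float = 1e-4
    n_pos_per_image: int = 2
    n_neg_per_image: int = 3
    n_part_per_image: int = 1
    # mine stage-2 windows from trained stage-1 candidates so the refinement
    # network trains on the candidate distribution it will actually see
    stage2_from_stage1: bool = True
    max_candidates_per_image: int = 6
    seed: int = 0


def _window_dataset(samples: list[PhantomSample], cfg: DetectorTrainConfig,
                    out_size: int, rng: np.random.Generator):
    crops, labels, boxes, kps = [], [], [], []
    for s in samples:
        wins = sample_detector_windows(s, cfg.n_pos_per_image,
                                       cfg.n_neg_per_image, rng,
                                       n_part=cfg.n_part_per_image)
        for win in wins:
            crops.append(crop_window(s.image.pixels, win.box, out_size))
            labels.append(win.label)
            boxes.append(win.offsets if win.offsets is not None else np.zeros(4))
            kps.append(win.keypoints if win.keypoints is not None else np.zeros(12))
    return (np.stack(crops), np.asarray(labels),
            np.stack(boxes), np.stack(kps))


def _train_stage(net, crops, labels, boxes, kps, alphas, lr, cfg,
                 rng: np.random.Generator, stage: int,
                 log: list[dict] | None = None):
    opt = nn.Adam(net.parameters(), lr=lr, weight_decay=cfg.weight_decay)
    n = len(crops)
    a_det, a_box, a_kp = alphas
    net.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = _normalize(crops[idx][:, None])
            if stage == 1:
                out = net.forward(x)
                pred = {"logit": out[:, 0, 0, 0], "box": out[:, 1:5, 0, 0]}
            else:
                pred = net.forward(x)
            target = {"label": labels[idx], "box": boxes[idx], "kp": kps[idx]}
            loss, grads = multitask_loss(pred, target, a_det, a_box, a_kp,
                                         return_grads=True)
            net.zero_grad()
            if stage == 1:
                gmap = np.zeros((len(idx), 5, 1, 1))
                gmap[:, 0, 0, 0] = grads["logit"]
                gmap[:, 1:5, 0, 0] = grads["box"]
                net.backward(gmap)
            else:
                net.backward(grads)
            opt.step()
            total += loss * len(idx)
        if log is not None:
            log.append({"stage": stage, "epoch": epoch + 1, "loss": total / n})
    net.eval()


def _mine_stage2_windows(samples: list[PhantomSample], stage1: Stage1Net,
                         config: CascadeConfig, cfg: DetectorTrainConfig,
                         out_size: int):
    """Label stage-1 candidate squares against truth: IoU >= 0.65 positive
    (box + key-point targets), < 0.3 negative, in between part (box only)."""
    crops, labels, boxes, kps = [], [], [], []
    for s in samples:
        cands = _stage1_candidates(s.image.pixels, stage1, config)
        cands = nms(cands, config.nms_iou_stage1)[:cfg.max_candidates_per_image]
        for c in cands:
            sq = to_square(c.box)
            side = sq[2] - sq[0]
            if side < 4:
                continue
            ov = iou(sq, s.box)
            if ov >= 0.65:
                label = 1
            elif ov < 0.3:
                label = 0
            else:
                label = -1
            off = (np.array([s.box[0] - sq[0], s.box[1] - sq[1],
                             s.box[2] - sq[2], s.box[3] - sq[3]]) / side)
            kp = ((s.keypoints - sq[:2]) / side).reshape(-1)
            crops.append(crop_window(s.image.pixels, sq, out_size))
            labels.append(label)
            boxes.append(off)
            kps.append(kp if label == 1 else np.zeros(12))
    if not crops:
        return None
    return np.stack(crops), np.asarray(labels), np.stack(boxes), np.stack(kps)


def _stage1_candidates(pixels: np.ndarray, stage1: Stage1Net,
                       config: CascadeConfig) -> list[Detection]:
    stage1.eval()
    cands: list[Detection] = []
    for scale, resized in build_pyramid(pixels, config):
        out = stage1.forward(_normalize(resized[None, None]))
        probs = sigmoid(out[0, 0])
        side = config.stage1_input_size / scale
        ys, xs = np.nonzero(probs >= config.stage1_score_threshold)
        for i, j in zip(ys, xs):
            x1 = j * Stage1Net.STRIDE / scale
            y1 = i * Stage1Net.STRIDE / scale
            win = np.array([x1, y1, x1 + side, y1 + side])
            box = win + out[0, 1:5, i, j] * side
            if box[2] > box[0] and box[3] > box[1]:
                cands.append(Detection(box, float(probs[i, j])))
    return cands


def train_detector(samples: list[PhantomSample], config: CascadeConfig,
                   train_cfg: DetectorTrainConfig | None = None,
                   log: list[dict] | None = None
                   ) -> tuple[Stage1Net, Stage2Net]:
    """Train both cascade stages on mined phantom windows.

    Stage 1 uses loss weights (1, 0.5, 0) — no key-point term; stage 2 uses
    (0.8, 0.6, 1.5). Each stage trains for ``epochs`` epochs with Adam.
    """
    cfg = train_cfg or DetectorTrainConfig()
    rng = np.random.default_rng(cfg.seed)
    stage1 = Stage1Net(config, np.random.default_rng(cfg.seed + 1))
    stage2 = Stage2Net(config, np.random.default_rng(cfg.seed + 2))

    crops1, labels, boxes, kps = _window_dataset(samples, cfg,
                                                 config.stage1_input_size, rng)
    _train_stage(stage1, crops1, labels, boxes, kps, config.stage1_alphas,
                 cfg.lr_stage1, cfg, rng, stage=1, log=log)

    rng2 = np.random.default_rng(cfg.seed + 3)
    crops2, labels2, boxes2, kps2 = _window_dataset(samples, cfg,
                                                    config.stage2_input_size, rng2)
    if cfg.stage2_from_stage1:
        mined = _mine_stage2_windows(samples, stage1, config, cfg,
                                     config.stage2_input_size)
        if mined is not None:
            crops2 = np.concatenate([crops2, mined[0]])
            labels2 = np.concatenate([labels2, mined[1]])
            boxes2 = np.concatenate([boxes2, mined[2]])
            kps2 = np.concatenate([kps2, mined[3]])
    _train_stage(stage2, crops2, labels2, boxes2, kps2, config.stage2_alphas,
                 cfg.lr_stage2, cfg, rng2, stage=2, log=log)
    return stage1, stage2
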