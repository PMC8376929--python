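"""Training protocol for the grading network.

The schedule mirrors transfer-learning practice: epochs 1-2 train only the FC
layers (fusion gate + task heads) at lr 0.01 with the backbone frozen, epoch 3
unfreezes everything at lr 0.001, and from epoch 4 the rate drops to 0.0001.
Adam with weight decay 1e-4 throughout; dropout 0.5 sits before every FC head.
The multi-task objective is an (optionally weighted) sum of per-task
cross-entropies; rows with a missing label for a task are masked out of that
task's term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .grader import TASKS, GlobalGrader, SiameseGrader
from .nn.losses import softmax_cross_entropy


@dataclass
class AugmentConfig:
    contrast: bool = True
    gamma: bool = True
    rotation: bool = True
    translation: bool = True
    contrast_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.7, 1.3)
    rotation_deg: float = 10.0
    translation_frac: float = 0.05

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(contrast=False, gamma=False, rotation=False, translation=False)


@dataclass
class TrainConfig:
    epochs: int = 20
    # (first_epoch, last_epoch, lr, scope); scope is "fc_only" or "all"
    schedule: tuple = ((1, 2, 0.01, "fc_only"), (3, 3, 0.001, "all"),
                      (4, 10 ** 9, 0.0001, "all"))
    weight_decay: float = 1e-4
    batch_size: int = 32
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    task_weights: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t, _ in TASKS})

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def tiny_train_config(seed: int = 0) -> TrainConfig:
    """Training protocol for the from-scratch ``tiny`` profile.

    Keeps the transfer-learning structure (two FC-only epochs with a frozen
    backbone, then full training) but holds a larger constant rate afterwards:
    the default schedule's decay to 1e-4 assumes a pretrained backbone; a
    randomly initialized network is still far from convergence. Geometric
    augmentation is off because the phantom generator already jitters pose.
    """
    return TrainConfig(
        epochs=60, batch_size=16, seed=seed,
        schedule=((1, 2, 0.01, "fc_only"), (3, 10 ** 9, 0.003, "all")),
        augment=AugmentConfig(rotation=False, translation=False))


def lr_schedule(epoch: int, cfg: TrainConfig) -> tuple[float, str]:
    """Learning rate and trainable scope for a 1-based epoch index."""
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside 1..{cfg.epochs}")
    for first, last, lr, scope in cfg.schedule:
        if first <= epoch <= last:
            if lr <= 0:
                raise ValueError("learning rate must be positive")
            return lr, scope
    raise ValueError(f"schedule does not cover epoch {epoch}")


def grading_loss(logits: dict[str, np.ndarray], labels: dict[str, np.ndarray],
                 task_weights: dict[str, float] | None = None,
                 return_grads: bool = False):
    """Sum of per-task cross-entropies; labels < 0 mark missing annotations.

    Returns the scalar loss (and per-task logit gradients when requested).
    Raises if every task is fully masked.
    """
    weights = task_weights or {t: 1.0 for t, _ in TASKS}
    total = 0.0
    grads = {}
    any_valid = False
    for task, _k in TASKS:
        lab = np.asarray(labels[task])
        valid = lab >= 0
        grads[task] = np.zeros_like(logits[task])
        w = weights.get(task, 1.0)
        if not valid.any() or w == 0.0:
            continue
        any_valid = True
        loss, d = softmax_cross_entropy(logits[task][valid], lab[valid], weight=w)
        total += loss
        grads[task][valid] = d
    if not any_valid:
        raise ValueError("all tasks masked: nothing to train on")
    if return_grads:
        return total, grads
    return total


def augment(img: np.ndarray, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> np.ndarray:
    """Photometric + geometric augmentation of one patch.

    Contrast scaling about the mean, gamma correction, small rotation and
    translation; each transform family can be switched off. Works on float
    images in [0, 1] (uint8 input is converted and returned as uint8).
    Deterministic for a fixed generator state.
    """
    cfg = cfg or AugmentConfig()
    was_uint8 = img.dtype == np.uint8
    x = img.astype(np.float64) / 255.0 if was_uint8 else img.astype(np.float64)
    if cfg.contrast:
        c = rng.uniform(*cfg.contrast_range)
        m = x.mean()
        x = np.clip(m + c * (x - m), 0.0, 1.0)
    if cfg.gamma:
        x = np.clip(x, 0.0, 1.0) ** rng.uniform(*cfg.gamma_range)
    if cfg.rotation:
        deg = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        x = ndimage.rotate(x, deg, reshape=False, order=1, mode="nearest")
    if cfg.translation:
        h, w = x.shape
        dy = rng.uniform(-cfg.translation_frac, cfg.translation_frac) * h
        dx = rng.uniform(-cfg.translation_frac, cfg.translation_frac) * w
        x = ndimage.shift(x, (dy, dx), order=1, mode="nearest")
    x = np.clip(x, 0.0, 1.0)
    return (np.round(x * 255.0)).astype(np.uint8) if was_uint8 else x


def _scope_params(model, scope: str):
    return model.fc_parameters() if scope == "fc_only" else model.parameters()


def _labels_batch(labels: dict[str, np.ndarray], idx: np.ndarray):
    return {t: labels[t][idx] for t, _ in TASKS}


def train_grader(data: dict, model: SiameseGrader | GlobalGrader,
                 cfg: TrainConfig | None = None) -> list[dict]:
    """Train a grader on phantom patches and return the per-epoch metric log.

    ``data['train']`` / ``data['val']`` are dicts with either ``left``/``right``
    (N,H,W) float stacks in [0,1] (Siamese) or ``roi`` (global), plus
    ``labels``: task -> (N,) int arrays. The model is left holding the weights
    of its best validation-loss epoch.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    siamese = isinstance(model, SiameseGrader)
    train, val = data["train"], data["val"]
    n = len(next(iter(train["labels"].values())))
    if n == 0:
        raise ValueError("empty training set")

    log: list[dict] = []
    best = (np.inf, None)
    current_mode = None
    opt = None
    for epoch in range(1, cfg.epochs + 1):
        lr, scope = lr_schedule(epoch, cfg)
        if (lr, scope) != current_mode:
            opt = nn.Adam(_scope_params(model, scope), lr=lr,
                          weight_decay=cfg.weight_decay)
            current_mode = (lr, scope)
        model.freeze_backbone = scope == "fc_only"
        model.train()
        order = rng.permutation(n)
        running = 0.0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            lab = _labels_batch(train["labels"], idx)
            if siamese:
                left = _augment_stack(train["left"][idx], rng, cfg.augment)
                right = _augment_stack(train["right"][idx], rng, cfg.augment)
                logits = model.forward(left[:, None] - 0.5, right[:, None] - 0.5)
            else:
                roi = _augment_stack(train["roi"][idx], rng, cfg.augment)
                logits = model.forward(roi[:, None] - 0.5)
            loss, grads = grading_loss(logits, lab, cfg.task_weights,
                                       return_grads=True)
            model.zero_grad()
            model.backward(grads)
            opt.step()
            running += loss * len(idx)

        entry = {"epoch": epoch, "lr": lr, "scope": scope,
                 "train_loss": running / n}
        entry.update(_validate(model, val, cfg, siamese))
        log.append(entry)
        if entry["val_loss"] < best[0]:
            best = (entry["val_loss"], model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.freeze_backbone = False
    model.eval()
    return log


def _augment_stack(stack: np.ndarray, rng: np.random.Generator,
                   acfg: AugmentConfig) -> np.ndarray:
    if not (acfg.contrast or acfg.gamma or acfg.rotation or acfg.translation):
        return stack
    return np.stack([augment(im, rng, acfg) for im in stack])


def _validate(model, val: dict, cfg: TrainConfig, siamese: bool) -> dict:
    from .metrics import top1, top_pm1

    model.eval()
    labels = val["labels"]
    nv = len(next(iter(labels.values())))
    all_logits = {t: [] for t, _ in TASKS}
    total = 0.0
    for s in range(0, nv, cfg.batch_size):
        if siamese:
            logits = model.forward(val["left"][s:s + cfg.batch_size, None] - 0.5,
                                   val["right"][s:s + cfg.batch_size, None] - 0.5)
        else:
            logits = model.forward(val["roi"][s:s + cfg.batch_size, None] - 0.5)
        lab = {t: labels[t][s:s + cfg.batch_size] for t, _ in TASKS}
        total += grading_loss(logits, lab, cfg.task_weights) * len(lab["kl"])
        for t, _ in TASKS:
            all_logits[t].append(logits[t])
    out = {"val_loss": total / nv}
    for t, _ in TASKS:
        pred = np.concatenate(all_logits[t]).argmax(axis=1)
        out[f"top1_{t}"] = top1(pred, labels[t])
        if t != "oa":
            out[f"top_pm1_{t}"] = top_pm1(pred, labels[t])
    return out
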