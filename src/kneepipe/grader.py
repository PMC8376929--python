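"""SE-ResNeXt Siamese grading network with adaptive gated feature fusion.

The grader consumes the two mirrored halves of a main-knee-joint crop through
one shared-weight backbone (a Siamese pair), fuses the two d-dimensional
feature vectors with a learned sigmoid gate

    g = sigmoid(W_g (f_left ++ f_right)),   f = g * f_left + (1 - g) * f_right

(elementwise; ++ is concatenation) and predicts eight tasks in parallel:
the composite Kellgren-Lawrence grade (5 classes), six OARSI feature grades
(4 classes each: lateral/medial joint-space narrowing and osteophytes at the
FL/FM/TL/TM sites) and the binary OA (KL>=2) task. Each head is dropout(0.5)
followed by a linear layer with softmax.

Backbone blocks combine the ResNeXt aggregated transform

    y = x + sum_{i=1..C} f_i(x)

(cardinality C, realized as a 1x1 reduce -> grouped 3x3 -> 1x1 expand
bottleneck) with squeeze-and-excitation channel reweighting: channel means
z_c are squeezed through a two-layer bottleneck (reduction ratio r) and a
sigmoid produces per-channel weights w that rescale the branch output before
the residual addition. The final block output is x + SE(branch), so a block
with zero transform weights is exactly the identity.

Two stage plans are provided: the full 50-layer plan (3,4,6,3 blocks, output
widths 256/512/1024/2048, cardinality 32, bottleneck width 4) and a ``tiny``
two-stage plan (widths 32/64) that trains in minutes on one CPU and is the
profile the test suite exercises end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn.losses import sigmoid, softmax

#: task -> number of classes, in fixed head order
TASKS: tuple[tuple[str, int], ...] = (
    ("kl", 5), ("jsn_l", 4), ("jsn_m", 4), ("fl", 4), ("fm", 4),
    ("tl", 4), ("tm", 4), ("oa", 2),
)
TASK_CLASSES = dict(TASKS)


@dataclass
class GraderConfig:
    profile: str = "full"            # "full" or "tiny"
    patch_size: int = 128
    cardinality: int = 32
    bottleneck_width: int = 4
    se_reduction: int = 16
    dropout: float = 0.5

    def __post_init__(self):
        if self.profile not in ("full", "tiny"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.cardinality < 1:
            raise ValueError("cardinality must be >= 1")


def tiny_grader_config(patch_size: int = 64) -> GraderConfig:
    return GraderConfig(profile="tiny", patch_size=patch_size, cardinality=4,
                        bottleneck_width=4, se_reduction=8)


@dataclass
class GradePrediction:
    """Per-task probability vectors plus argmax grades."""

    probs: dict[str, np.ndarray]
    grades: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for task, k in TASKS:
            p = np.asarray(self.probs[task], dtype=np.float64)
            if p.shape != (k,) or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
                raise ValueError(f"invalid probability vector for task {task}")
            self.probs[task] = p
        if not self.grades:
            self.grades = {t: int(np.argmax(self.probs[t])) for t, _ in TASKS}


# ---------------------------------------------------------------------------
# blocks


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel recalibration.

    Squeeze: z_c = mean over HxW of channel c. Excite: w = sigmoid(W2 relu(W1 z))
    with W1 reducing C -> C/r and W2 restoring. Scale: out_c = w_c * p_c.
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)
        self._cache = None

    def forward(self, p: np.ndarray) -> np.ndarray:
        n, c, h, w_ = p.shape
        z = p.mean(axis=(2, 3))
        u = self.fc2.forward(self.relu.forward(self.fc1.forward(z)))
        w = 1.0 / (1.0 + np.exp(-u))
        self._cache = (p, w, h * w_)
        return p * w[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        p, w, hw = self._cache
        dp = grad * w[:, :, None, None]
        dw = (grad * p).sum(axis=(2, 3))
        du = dw * w * (1.0 - w)
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(du)))
        dp += dz[:, :, None, None] / hw
        return dp


class ResNextBlock(nn.Module):
    """Aggregated-transform residual block in grouped-convolution form.

    ``cardinality`` parallel bottleneck transforms (1x1 reduce to
    cardinality*width channels, grouped 3x3, 1x1 expand) are realized as one
    grouped convolution; their sum is SE-reweighted and added to the shortcut
    (identity, or a 1x1 projection when channel counts differ).
    """

    def __init__(self, in_channels: int, out_channels: int, cardinality: int = 32,
                 width: int = 4, se_reduction: int | None = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        mid = cardinality * width
        self.reduce = nn.Conv2d(in_channels, mid, 1, rng=rng)
        self.relu1 = nn.ReLU()
        self.grouped = nn.Conv2d(mid, mid, 3, padding=1, groups=cardinality, rng=rng)
        self.relu2 = nn.ReLU()
        self.expand = nn.Conv2d(mid, out_channels, 1, rng=rng)
        self.se = (SEBlock(out_channels, se_reduction, rng=rng)
                   if se_reduction else None)
        self.proj = (nn.Conv2d(in_channels, out_channels, 1, rng=rng)
                     if in_channels != out_channels else None)
        self.cardinality, self.width = cardinality, width

    def branch(self, x: np.ndarray) -> np.ndarray:
        """The aggregated transform sum_{i} f_i(x) (before SE and shortcut)."""
        t = self.relu1.forward(self.reduce.forward(x))
        t = self.relu2.forward(self.grouped.forward(t))
        return self.expand.forward(t)

    def forward(self, x: np.ndarray) -> np.ndarray:
        t = self.branch(x)
        if self.se is not None:
            t = self.se.forward(t)
        s = self.proj.forward(x) if self.proj is not None else x
        return s + t

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dt = self.se.backward(grad) if self.se is not None else grad
        dt = self.expand.backward(dt)
        dt = self.grouped.backward(self.relu2.backward(dt))
        dx = self.reduce.backward(self.relu1.backward(dt))
        dx = dx + (self.proj.backward(grad) if self.proj is not None else grad)
        return dx


_STAGE_PLANS = {
    # (blocks per stage, out width per stage, bottleneck width per stage)
    "full": ((3, 4, 6, 3), (256, 512, 1024, 2048), (4, 8, 16, 32)),
    "tiny": ((1, 1), (32, 64), (4, 8)),
}
# stem: channels, kernel, stride. The tiny stem downsamples immediately so
# the feature grid entering global pooling is 4x4 at the default 64px patch;
# with coarser pooling each informative cell carries more of the channel mean,
# which is what lets the network pick up the few-pixel osteophyte bumps.
_STEM = {"full": (64, 7, 2), "tiny": (16, 3, 2)}


def build_backbone(config: GraderConfig, rng: np.random.Generator) -> tuple[nn.Sequential, int]:
    """Stem -> SE-ResNeXt stages (max-pool downsampling between stages) ->
    global average pooling. Returns (network, feature dimension d)."""
    blocks_per, widths, bws = _STAGE_PLANS[config.profile]
    stem_ch, stem_k, stem_s = _STEM[config.profile]
    layers: list[nn.Module] = [
        nn.Conv2d(1, stem_ch, stem_k, stride=stem_s, padding=stem_k // 2, rng=rng),
        nn.ReLU(), nn.MaxPool2d(2),
    ]
    in_ch = stem_ch
    for n_blocks, width_out, bw in zip(blocks_per, widths, bws):
        for b in range(n_blocks):
            layers.append(ResNextBlock(in_ch, width_out, config.cardinality,
                                       bw, config.se_reduction, rng=rng))
            in_ch = width_out
        layers.append(nn.MaxPool2d(2))
    layers.append(nn.GlobalAvgPool2d())
    return nn.Sequential(*layers), in_ch


# ---------------------------------------------------------------------------
# fusion


def gated_fuse(f_left: np.ndarray, f_right: np.ndarray, w_g: np.ndarray,
               bias: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive gated fusion of two feature vectors (pure-numpy form).

    ``w_g`` maps the concatenated 2d-vector to a d-vector of gate logits;
    returns (fused feature f, gate g) with f = g*f_left + (1-g)*f_right.
    """
    f_left = np.asarray(f_left, float)
    f_right = np.asarray(f_right, float)
    if f_left.shape != f_right.shape:
        raise ValueError("feature length mismatch")
    d = f_left.shape[-1]
    if w_g.shape != (d, 2 * d):
        raise ValueError(f"W_g must be (d, 2d) = ({d}, {2 * d}), got {w_g.shape}")
    cat = np.concatenate([f_left, f_right], axis=-1)
    u = cat @ w_g.T
    if bias is not None:
        u = u + bias
    g = sigmoid(u)
    return g * f_left + (1.0 - g) * f_right, g


# ---------------------------------------------------------------------------
# models


class _Heads(nn.Module):
    """Eight parallel dropout+linear task heads over one fused feature."""

    def __init__(self, d: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.drops = [nn.Dropout(dropout, rng=rng) for _ in TASKS]
        self.linears = [nn.Linear(d, k, rng=rng) for _, k in TASKS]
        for lin in self.linears:  # start classifier logits near uniform
            lin.weight.data *= 0.1

    def forward(self, f: np.ndarray) -> dict[str, np.ndarray]:
        return {task: lin.forward(drop.forward(f))
                for (task, _), drop, lin in zip(TASKS, self.drops, self.linears)}

    def backward(self, dlogits: dict[str, np.ndarray]) -> np.ndarray:
        df = None
        for (task, _), drop, lin in zip(TASKS, self.drops, self.linears):
            g = drop.backward(lin.backward(dlogits[task]))
            df = g if df is None else df + g
        return df


class SiameseGrader(nn.Module):
    """Shared-weight Siamese SE-ResNeXt with gated fusion and eight heads."""

    def __init__(self, config: GraderConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or GraderConfig()
        rng = np.random.default_rng(seed)
        self.backbone, self.d = build_backbone(self.config, rng)
        self.fuse = nn.Linear(2 * self.d, self.d, rng=rng)
        self.heads = _Heads(self.d, self.config.dropout, rng)
        self.freeze_backbone = False
        self._cache = None

    def forward(self, left: np.ndarray, right: np.ndarray) -> dict[str, np.ndarray]:
        """(N,1,H,W) patch pairs -> dict of per-task logits.

        Both patches pass through the one backbone as a single 2N batch, which
        is what weight sharing means operationally.
        """
        n = left.shape[0]
        feats = self.backbone.forward(np.concatenate([left, right], axis=0))
        f_l, f_r = feats[:n], feats[n:]
        u = self.fuse.forward(np.concatenate([f_l, f_r], axis=1))
        g = 1.0 / (1.0 + np.exp(-u))
        fused = g * f_l + (1.0 - g) * f_r
        self._cache = (n, f_l, f_r, g)
        return self.heads.forward(fused)

    def backward(self, dlogits: dict[str, np.ndarray]) -> None:
        n, f_l, f_r, g = self._cache
        dfused = self.heads.backward(dlogits)
        dg = dfused * (f_l - f_r)
        df_l = dfused * g
        df_r = dfused * (1.0 - g)
        du = dg * g * (1.0 - g)
        dcat = self.fuse.backward(du)
        df_l = df_l + dcat[:, :self.d]
        df_r = df_r + dcat[:, self.d:]
        if not self.freeze_backbone:
            self.backbone.backward(np.concatenate([df_l, df_r], axis=0))

    def fc_parameters(self) -> list[nn.Parameter]:
        """Parameters of the fusion gate and task heads (the FC layers)."""
        return self.fuse.parameters() + self.heads.parameters()


class GlobalGrader(nn.Module):
    """Single-branch variant: the whole main knee joint through one backbone."""

    def __init__(self, config: GraderConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or GraderConfig()
        rng = np.random.default_rng(seed)
        self.backbone, self.d = build_backbone(self.config, rng)
        self.heads = _Heads(self.d, self.config.dropout, rng)
        self.freeze_backbone = False

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        return self.heads.forward(self.backbone.forward(x))

    def backward(self, dlogits: dict[str, np.ndarray]) -> None:
        df = self.heads.backward(dlogits)
        if not self.freeze_backbone:
            self.backbone.backward(df)

    def fc_parameters(self) -> list[nn.Parameter]:
        return self.heads.parameters()


# ---------------------------------------------------------------------------
# prediction helpers


def logits_to_predictions(logits: dict[str, np.ndarray]) -> list[GradePrediction]:
    n = next(iter(logits.values())).shape[0]
    out = []
    for i in range(n):
        probs = {t: softmax(logits[t][i]) for t, _ in TASKS}
        out.append(GradePrediction(probs=probs))
    return out


def predict_pairs(model: SiameseGrader, lefts: np.ndarray, rights: np.ndarray,
                  batch_size: int = 64) -> list[GradePrediction]:
    """Eval-mode batched prediction on (N,H,W) patch stacks in [0, 1]."""
    model.eval()
    preds: list[GradePrediction] = []
    for s in range(0, len(lefts), batch_size):
        logits = model.forward(lefts[s:s + batch_size, None] - 0.5,
                               rights[s:s + batch_size, None] - 0.5)
        preds.extend(logits_to_predictions(logits))
    return preds


def predict_global(model: GlobalGrader, rois: np.ndarray,
                   batch_size: int = 64) -> list[GradePrediction]:
    model.eval()
    preds: list[GradePrediction] = []
    for s in range(0, len(rois), batch_size):
        logits = model.forward(rois[s:s + batch_size, None] - 0.5)
        preds.extend(logits_to_predictions(logits))
    return preds


def ensemble_predict(pred_a: GradePrediction, pred_b: GradePrediction) -> GradePrediction:
    """Global + Siamese ensemble: arithmetic mean of per-task probabilities."""
    probs = {}
    for task, k in TASKS:
        pa, pb = pred_a.probs[task], pred_b.probs[task]
        if pa.shape != pb.shape:
            raise ValueError(f"task space mismatch for {task}")
        probs[task] = (pa + pb) / 2.0
    return GradePrediction(probs=probs)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SiameseGrader | GlobalGrader, path: str | Path) -> None:
    cfg = {"kind": type(model).__name__, **model.config.__dict__}
    np.savez(Path(path), __config__=json.dumps(cfg), **model.state_dict())


def load_checkpoint(path: str | Path) -> SiameseGrader | GlobalGrader:
    data = np.load(Path(path), allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    kind = cfg.pop("kind")
    config = GraderConfig(**cfg)
    model = SiameseGrader(config) if kind == "SiameseGrader" else GlobalGrader(config)
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model.eval()
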