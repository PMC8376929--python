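"""Synthetic knee-phantom generator with exact ground truth.

Real knee radiograph collections (OAI, MOST) are access restricted, so the
pipeline is exercised on deterministic phantoms that reproduce the structure
the method consumes: bright femur/tibia masses on a dark background (with an
optional inverted-polarity variant), a two-compartment joint space whose gap
narrows with the joint-space-narrowing (JSN) grade, corner osteophyte
protrusions whose size grows with the osteophyte grade, six key points on the
joint margins and left/right anatomical symmetry.

Geometry of a single-knee phantom (canvas 256x256 by default, y down):

* femur: rounded rectangle whose bottom edge sits ``gap`` pixels above the
  tibial plateau; the gap differs between the lateral (image-left) and medial
  (image-right) compartments, ``gap = base_gap * (1 - 0.25 * jsn_grade)``;
* tibia: rounded rectangle below the plateau with two triangular tibial
  spines near the midline;
* osteophytes: semicircular bumps of radius ``2 * grade + 1`` px at the four
  compartment corners (FL, FM, TL, TM sites);
* key points (fixed order): lateral/medial femoral margin, lateral/medial
  tibial margin, lateral/medial tibial spine.

Every sample carries the exact post-jitter bounding box, key points and an
eight-task label vector whose composite Kellgren-Lawrence (KL) grade follows
the deterministic surrogate ``KL = min(4, max(osteophytes) + max(JSN))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import KneeImage

OSTEO_TASKS = ("fl", "fm", "tl", "tm")
JSN_TASKS = ("jsn_l", "jsn_m")
GRADE_TASKS = OSTEO_TASKS + JSN_TASKS
DEFAULT_MARGINALS = (0.45, 0.25, 0.15, 0.15)


@dataclass
class PhantomSpec:
    """Parameters from which one labeled phantom is rendered deterministically."""

    image_size: tuple[int, int] = (256, 256)   # (H, W) single knee
    base_gap: float = 24.0
    jsn_l: int = 0
    jsn_m: int = 0
    fl: int = 0
    fm: int = 0
    tl: int = 0
    tm: int = 0
    bone_intensity: int = 200
    background_intensity: int = 20
    noise_sd: float = 6.0
    blur_sigma: float = 1.2
    polarity: str = "dark"
    max_shift: float = 12.0        # translation jitter, px
    max_rotation: float = 2.0      # rotation jitter, degrees
    knee_width_range: tuple[float, float] = (140.0, 170.0)
    bone_height_range: tuple[float, float] = (75.0, 95.0)

    def __post_init__(self):
        for task in GRADE_TASKS:
            g = getattr(self, task)
            if not 0 <= g <= 3:
                raise ValueError(f"{task} grade {g} out of range 0..3")
        if self.base_gap * (1 - 0.25 * 3) < 2:
            raise ValueError("base_gap too small: grade-3 gap would collapse")
        if self.polarity not in ("dark", "bright"):
            raise ValueError(f"bad polarity {self.polarity!r}")

    @property
    def labels(self) -> dict[str, int]:
        osteo = max(self.fl, self.fm, self.tl, self.tm)
        jsn = max(self.jsn_l, self.jsn_m)
        kl = min(4, osteo + jsn)
        return {"kl": kl, "jsn_l": self.jsn_l, "jsn_m": self.jsn_m,
                "fl": self.fl, "fm": self.fm, "tl": self.tl, "tm": self.tm,
                "oa": int(kl >= 2)}

    def gap(self, compartment: str) -> float:
        grade = self.jsn_l if compartment == "lateral" else self.jsn_m
        return self.base_gap * (1.0 - 0.25 * grade)


@dataclass
class PhantomSample:
    image: KneeImage
    box: np.ndarray            # [x1, y1, x2, y2], half-open
    keypoints: np.ndarray      # (6, 2) x,y
    labels: dict[str, int]
    spec: PhantomSpec = field(repr=False, default=None)


def _rounded_rect_mask(shape, y0, y1, x0, x1, radius):
    """Half-open rounded rectangle [y0, y1) x [x0, x1): boundary coordinates
    are bone/background transitions, so a geometric gap of g renders as
    exactly g background rows."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    iy = np.clip(yy, y0 + radius, y1 - 1 - radius)
    ix = np.clip(xx, x0 + radius, x1 - 1 - radius)
    inside = (yy >= y0) & (yy < y1) & (xx >= x0) & (xx < x1)
    corner_ok = (yy - iy) ** 2 + (xx - ix) ** 2 <= radius ** 2
    return inside & corner_ok


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def render_bone_mask(spec: PhantomSpec, knee_width: float, bone_height: float,
                     cx: float, cy: float) -> tuple[np.ndarray, np.ndarray, dict]:
    """Noiseless geometry: returns (femur_mask, tibia_mask, geometry dict)."""
    h, w = spec.image_size
    shape = (h, w)
    half = knee_width / 2.0
    x_lat, x_med = cx - half, cx + half
    plateau = cy + spec.base_gap / 2.0                    # tibia top edge
    fb_lat = plateau - spec.gap("lateral")                # femur bottom, lateral
    fb_med = plateau - spec.gap("medial")

    yy, xx = np.mgrid[0:h, 0:w]
    lateral_cols = xx < cx
    rc = 10
    femur_lat = _rounded_rect_mask(shape, fb_lat - bone_height, fb_lat, x_lat, x_med, rc)
    femur_med = _rounded_rect_mask(shape, fb_med - bone_height, fb_med, x_lat, x_med, rc)
    femur = np.where(lateral_cols, femur_lat, femur_med)
    tibia = _rounded_rect_mask(shape, plateau, plateau + bone_height, x_lat, x_med, rc)

    # tibial spines: triangular peaks flanking the midline
    spine_dx, spine_h, spine_w = 12.0, 14.0, 12.0
    for sx in (cx - spine_dx, cx + spine_dx):
        rel = (yy - (plateau - spine_h)) / spine_h        # 0 at peak, 1 at base
        tri = (rel >= 0) & (rel <= 1) & (np.abs(xx - sx) <= (spine_w / 2) * rel)
        tibia |= tri

    # osteophytes: semicircular protrusions at the four compartment corners
    for site, (ocx, ocy) in {
        "fl": (x_lat, fb_lat), "fm": (x_med, fb_med),
        "tl": (x_lat, plateau), "tm": (x_med, plateau),
    }.items():
        r = 2 * getattr(spec, site) + 1
        bump = _disk_mask(shape, ocy, ocx, r)
        if site.startswith("f"):
            femur |= bump & (yy <= ocy)    # keep the joint space open
        else:
            tibia |= bump & (yy >= ocy)

    geom = {
        "x_lat": x_lat, "x_med": x_med, "plateau": plateau,
        "fb_lat": fb_lat, "fb_med": fb_med, "cx": cx,
        "spine_dx": spine_dx, "spine_h": spine_h,
    }
    return femur, tibia, geom


def _keypoints_from_geom(geom: dict) -> np.ndarray:
    """Six (x, y) key points in the fixed order: lateral/medial femoral margin,
    lateral/medial tibial margin, lateral/medial tibial spine."""
    return np.array([
        [geom["x_lat"], geom["fb_lat"]],
        [geom["x_med"], geom["fb_med"]],
        [geom["x_lat"], geom["plateau"]],
        [geom["x_med"], geom["plateau"]],
        [geom["cx"] - geom["spine_dx"], geom["plateau"] - geom["spine_h"]],
        [geom["cx"] + geom["spine_dx"], geom["plateau"] - geom["spine_h"]],
    ], dtype=np.float64)


def render_phantom(spec: PhantomSpec, rng: np.random.Generator,
                   clean: bool = False) -> PhantomSample:
    """Render one single-knee phantom with exact post-jitter ground truth.

    ``clean=True`` disables jitter, blur and noise (used by geometry oracles).
    """
    h, w = spec.image_size
    knee_width = rng.uniform(*spec.knee_width_range)
    bone_height = rng.uniform(*spec.bone_height_range)
    if clean:
        dx = dy = theta = 0.0
    else:
        dx = rng.uniform(-spec.max_shift, spec.max_shift)
        dy = rng.uniform(-spec.max_shift, spec.max_shift)
        theta = np.deg2rad(rng.uniform(-spec.max_rotation, spec.max_rotation))
    cx, cy = w / 2.0 + dx, h / 2.0 + dy

    femur, tibia, geom = render_bone_mask(spec, knee_width, bone_height, cx, cy)
    img = np.full((h, w), float(spec.background_intensity))
    img[femur | tibia] = float(spec.bone_intensity)
    kps = _keypoints_from_geom(geom)

    margin = 6.0
    ys, xs = np.nonzero(femur | tibia)
    box = np.array([xs.min() - margin, ys.min() - margin,
                    xs.max() + 1 + margin, ys.max() + 1 + margin])

    if theta != 0.0:
        img, kps, box = _rotate_about_center(img, kps, box, theta,
                                             float(spec.background_intensity))
    box = np.clip(box, [0, 0, 0, 0], [w, h, w, h]).astype(np.float64)

    if not clean:
        if spec.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    polarity = "dark_background"
    if spec.polarity == "bright":
        img = (255 - img.astype(np.int64)).astype(np.uint8)
        polarity = "bright_background"
    knee = KneeImage(img, bit_depth=8, polarity=polarity, side="left",
                     source_id="phantom")
    return PhantomSample(image=knee, box=box, keypoints=kps,
                         labels=spec.labels, spec=spec)


def _rotate_about_center(img, kps, box, theta, cval):
    h, w = img.shape
    c = np.array([w / 2.0, h / 2.0])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    # ndimage maps output coords through the matrix; supply the inverse rotation
    # in (row, col) order so image content rotates by +theta in x,y coords.
    rot_rc = np.array([[np.cos(theta), np.sin(theta)],
                       [-np.sin(theta), np.cos(theta)]])
    offset = np.array([h / 2.0, w / 2.0]) - rot_rc @ np.array([h / 2.0, w / 2.0])
    out = ndimage.affine_transform(img, rot_rc, offset=offset, order=1,
                                   mode="constant", cval=cval)
    kps = (kps - c) @ rot.T + c
    corners = np.array([[box[0], box[1]], [box[2], box[1]],
                        [box[0], box[3]], [box[2], box[3]]])
    corners = (corners - c) @ rot.T + c
    box = np.array([corners[:, 0].min(), corners[:, 1].min(),
                    corners[:, 0].max(), corners[:, 1].max()])
    return out, kps, box


def sample_spec(rng: np.random.Generator,
                marginals: tuple[float, ...] = DEFAULT_MARGINALS,
                polarity_mix: float = 0.0,
                correlation: float = 0.0,
                image_size: tuple[int, int] = (256, 256)) -> PhantomSpec:
    """Draw per-task grades (independent by default) and nuisance parameters.

    ``correlation`` in [0, 1] mixes in a shared latent severity: with
    probability ``correlation`` each task's grade is replaced by a common draw.
    """
    if not np.isclose(sum(marginals), 1.0):
        raise ValueError("grade marginals must sum to 1")
    grades = {t: int(rng.choice(4, p=marginals)) for t in GRADE_TASKS}
    if correlation > 0:
        shared = int(rng.choice(4, p=marginals))
        for t in GRADE_TASKS:
            if rng.random() < correlation:
                grades[t] = shared
    polarity = "bright" if rng.random() < polarity_mix else "dark"
    return PhantomSpec(image_size=image_size, polarity=polarity, **grades)


def generate_samples(n: int, seed: int, marginals=DEFAULT_MARGINALS,
                     polarity_mix: float = 0.0, correlation: float = 0.0,
                     image_size: tuple[int, int] = (256, 256),
                     clean: bool = False) -> list[PhantomSample]:
    """Generate ``n`` single-knee phantoms, deterministically from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = sample_spec(rng, marginals, polarity_mix, correlation, image_size)
        s = render_phantom(spec, rng, clean=clean)
        s.image.source_id = f"phantom_{i:05d}"
        out.append(s)
    return out


def compose_double(left: PhantomSample, right: PhantomSample) -> tuple[KneeImage, list[PhantomSample]]:
    """Place two single-knee phantoms side by side into one double-knee frame.

    Ground truth of the right knee is shifted by the left canvas width. If
    either half was rendered bright, the whole composite is stored bright
    (real scanners invert whole frames, not halves).
    """
    li, ri = left.image.pixels, right.image.pixels
    if li.shape[0] != ri.shape[0]:
        raise ValueError("half heights differ")
    bright = (left.image.polarity == "bright_background"
              or right.image.polarity == "bright_background")

    def as_dark(img: KneeImage):
        if img.polarity == "bright_background":
            return 255 - img.pixels.astype(np.int64)
        return img.pixels.astype(np.int64)

    canvas = np.hstack([as_dark(left.image), as_dark(right.image)])
    polarity = "dark_background"
    if bright:
        canvas = 255 - canvas
        polarity = "bright_background"
    double = KneeImage(canvas.astype(np.uint8), bit_depth=8, polarity=polarity,
                       side="double", source_id=left.image.source_id)
    off = li.shape[1]
    shifted = PhantomSample(
        image=right.image, box=right.box + np.array([off, 0, off, 0]),
        keypoints=right.keypoints + np.array([off, 0.0]), labels=right.labels,
        spec=right.spec)
    return double, [left, shifted]


def assign_splits(labels_kl: np.ndarray, seed: int,
                  ratios: tuple[int, int, int] = (5, 1, 3)) -> np.ndarray:
    """Stratified train/val/test assignment with the given integer ratios."""
    rng = np.random.default_rng(seed)
    names = np.array(["train", "val", "test"])
    total = sum(ratios)
    bounds = np.cumsum(ratios) / total
    split = np.empty(len(labels_kl), dtype=object)
    for kl in np.unique(labels_kl):
        idx = np.nonzero(labels_kl == kl)[0]
        rng.shuffle(idx)
        pos = np.arange(len(idx)) / max(len(idx), 1)
        split[idx] = names[np.searchsorted(bounds, pos, side="right")]
    return split.astype(str)


def generate_dataset(n: int, seed: int, out_dir: str | Path,
                     marginals=DEFAULT_MARGINALS, polarity_mix: float = 0.0,
                     correlation: float = 0.0) -> pd.DataFrame:
    """Write ``n`` phantoms to disk (PNG + labels CSV + keypoints JSON) and
    return the manifest with a stratified 5:1:3 train/val/test split."""
    from .image import write_png

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, seed, marginals, polarity_mix, correlation)
    rows, kp_records = [], {}
    for s in samples:
        name = f"{s.image.source_id}.png"
        write_png(s.image.with_(polarity="dark_background"), out_dir / name)
        rows.append({"knee_id": s.image.source_id, **s.labels})
        kp_records[s.image.source_id] = {
            "image": name,
            "box": [float(v) for v in s.box],
            "keypoints": [[float(x), float(y)] for x, y in s.keypoints],
        }
    df = pd.DataFrame(rows)
    df["split"] = assign_splits(df["kl"].to_numpy(), seed + 1)
    df.to_csv(out_dir / "labels.csv", index=False)
    with open(out_dir / "keypoints.json", "w") as fh:
        json.dump(kp_records, fh, indent=1)
    return df


# ---------------------------------------------------------------------------
# detector training windows


def _iou_xyxy(a, b) -> float:
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter) if inter > 0 else 0.0


@dataclass
class Window:
    """One square training window with detector targets."""

    box: np.ndarray             # [x1, y1, x2, y2] in image coords
    label: int                  # 1 knee, 0 non-knee
    offsets: np.ndarray | None  # (4,) normalized box regression target
    keypoints: np.ndarray | None  # (12,) normalized to the window
    iou: float = 0.0


def sample_detector_windows(sample: PhantomSample, n_pos: int, n_neg: int,
                            rng: np.random.Generator, n_part: int = 0,
                            pos_iou: float = 0.65, neg_iou: float = 0.3,
                            max_tries: int = 4000) -> list[Window]:
    """Mine square windows: positives with IoU >= ``pos_iou`` against the truth
    box (carrying box-offset and key-point targets), negatives < ``neg_iou``,
    and optional part windows in between (label -1, box targets only).

    Positive/part candidates are drawn around the truth box with generous
    scale (0.8-1.3x) and translation (±18% of the side) jitter so a detector
    trained on them tolerates the coarse stride of sliding-window scanning.
    """
    h, w = sample.image.shape
    tb = sample.box
    side_ref = max(tb[2] - tb[0], tb[3] - tb[1])
    cx, cy = (tb[0] + tb[2]) / 2.0, (tb[1] + tb[3]) / 2.0
    windows: list[Window] = []

    def offsets_for(win, side):
        off = np.array([tb[0] - win[0], tb[1] - win[1],
                        tb[2] - win[2], tb[3] - win[3]]) / side
        kp = (sample.keypoints - win[:2]) / side
        return off, kp.reshape(-1)

    got_pos = got_part = 0
    tries = 0
    while got_pos < n_pos or got_part < n_part:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not mine enough positive/part windows")
        side = side_ref * rng.uniform(0.8, 1.3)
        jx = cx + rng.uniform(-0.18, 0.18) * side
        jy = cy + rng.uniform(-0.18, 0.18) * side
        win = np.array([jx - side / 2, jy - side / 2, jx + side / 2, jy + side / 2])
        iou = _iou_xyxy(win, tb)
        if iou >= pos_iou and got_pos < n_pos:
            off, kp = offsets_for(win, side)
            windows.append(Window(win, 1, off, kp, iou))
            got_pos += 1
        elif 0.4 <= iou < pos_iou and got_part < n_part:
            off, _ = offsets_for(win, side)
            windows.append(Window(win, -1, off, None, iou))
            got_part += 1

    tries = 0
    got_neg = 0
    while got_neg < n_neg:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not mine enough negative windows")
        side = side_ref * rng.uniform(0.4, 1.2)
        x1 = rng.uniform(-side / 2, w - side / 2)
        y1 = rng.uniform(-side / 2, h - side / 2)
        win = np.array([x1, y1, x1 + side, y1 + side])
        if _iou_xyxy(win, tb) >= neg_iou:
            continue
        windows.append(Window(win, 0, None, None, _iou_xyxy(win, tb)))
        got_neg += 1
    return windows


def crop_window(image: np.ndarray, box: np.ndarray, out_size: int) -> np.ndarray:
    """Crop a (possibly out-of-bounds) square window, zero-padded, resized to
    ``out_size`` x ``out_size`` float64 in [0, 1]."""
    from skimage.transform import resize

    h, w = image.shape
    x1, y1, x2, y2 = (int(np.floor(box[0])), int(np.floor(box[1])),
                      int(np.ceil(box[2])), int(np.ceil(box[3])))
    out = np.zeros((y2 - y1, x2 - x1), dtype=np.float64)
    sx1, sy1 = max(x1, 0), max(y1, 0)
    sx2, sy2 = min(x2, w), min(y2, h)
    if sx2 > sx1 and sy2 > sy1:
        out[sy1 - y1:sy2 - y1, sx1 - x1:sx2 - x1] = image[sy1:sy2, sx1:sx2] / 255.0
    return resize(out, (out_size, out_size), order=1, mode="constant",
                  anti_aliasing=False)
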