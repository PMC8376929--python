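"""Radiograph normalization: polarity, double-knee splitting, intensity.

Raw knee radiographs arrive with inconsistent polarity (some scans render
bone dark on a bright field), mixed bit depths and both knees in one frame.
This module standardizes them to the form the detector consumes: 8-bit,
dark background / bright bone, one knee per image, histogram equalized.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from skimage import exposure

from .image import InvalidImageError, KneeImage, read_image, write_png

BORDER_FRACTION = 0.05
CENTER_FRACTION = 0.5


def classify_polarity(img: KneeImage) -> str:
    """Classify an image of unknown polarity from its intensity layout.

    The knee is centered and bone is the dominant bright object in a
    correctly polarized radiograph, so a border frame brighter than the
    central region indicates an inverted (bright-background) scan. The frame
    is 5% of each dimension wide; the central region is the middle 50%.
    """
    if img.polarity != "unknown":
        return img.polarity
    px = img.pixels.astype(np.float64)
    h, w = px.shape
    bh = max(1, int(round(h * BORDER_FRACTION)))
    bw = max(1, int(round(w * BORDER_FRACTION)))
    interior = np.zeros((h, w), dtype=bool)
    interior[bh:h - bh, bw:w - bw] = True
    border_mean = px[~interior].mean() if (~interior).any() else px.mean()
    ch, cw = int(round(h * CENTER_FRACTION)), int(round(w * CENTER_FRACTION))
    y0, x0 = (h - ch) // 2, (w - cw) // 2
    center_mean = px[y0:y0 + max(ch, 1), x0:x0 + max(cw, 1)].mean()
    return "bright_background" if border_mean > center_mean else "dark_background"


def normalize_polarity(img: KneeImage, force: bool = False) -> KneeImage:
    """Return the image in dark-background convention.

    Bright-background pixels are inverted as ``max_representable - p``. With
    ``force=True`` inversion is applied unconditionally (useful to verify the
    involution property).
    """
    polarity = "bright_background" if force else classify_polarity(img)
    if polarity == "bright_background":
        inverted = img.max_representable - img.pixels.astype(np.int64)
        return img.with_(pixels=inverted.astype(img.pixels.dtype),
                         polarity="dark_background")
    return img.with_(polarity="dark_background")


def split_double_knee(img: KneeImage) -> tuple[KneeImage, KneeImage]:
    """Split a double-knee frame at the vertical midline.

    For odd widths the right half receives the extra column. Note the image
    *left half* shows the subject's right knee on a standard AP radiograph;
    the ``side`` field records image-space position, which is what the rest
    of the pipeline keys on.
    """
    if img.side != "double":
        raise ValueError(f"split_double_knee requires side='double', got {img.side!r}")
    h, w = img.pixels.shape
    if w < 2:
        raise InvalidImageError("image too narrow to split")
    mid = w // 2
    left = img.with_(pixels=img.pixels[:, :mid].copy(), side="left")
    right = img.with_(pixels=img.pixels[:, mid:].copy(), side="right")
    return left, right


def standardize_intensity(img: KneeImage, clahe: bool = False) -> KneeImage:
    """Convert to 8-bit and apply (global) histogram equalization.

    16-bit input is first linearly min-max rescaled to [0, 255]. Equalization
    uses the 256-bin global histogram; with ``clahe=True`` contrast-limited
    adaptive equalization is used instead. A constant image maps to itself.
    """
    if img.polarity != "dark_background":
        raise ValueError("standardize_intensity requires dark_background polarity; "
                         "run normalize_polarity first")
    px = img.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        level = int(round(lo * 255.0 / img.max_representable))
        out = np.full(px.shape, level, dtype=np.uint8)
        return img.with_(pixels=out, bit_depth=8)
    scaled = (px - lo) / (hi - lo)  # [0, 1]
    if clahe:
        eq = exposure.equalize_adapthist(scaled)
    else:
        eq = exposure.equalize_hist(scaled, nbins=256)
    out = np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)
    return img.with_(pixels=out, bit_depth=8)


def preprocess_image(img: KneeImage, clahe: bool = False) -> list[KneeImage]:
    """Full preprocessing of one raw frame: polarity -> split -> standardize."""
    img = normalize_polarity(img)
    knees = list(split_double_knee(img)) if img.side == "double" else [img]
    return [standardize_intensity(k, clahe=clahe) for k in knees]


def preprocess_dir(in_dir: str | Path, out_dir: str | Path,
                   clahe: bool = False, layout: str = "double") -> list[Path]:
    """Preprocess every readable image in ``in_dir``; write 8-bit PNGs named
    ``<source_id>_<L|R>.png`` into ``out_dir``. Returns the written paths.

    ``layout='single'`` treats each frame as one knee (no midline split).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    side = "double" if layout == "double" else "left"
    written = []
    for path in sorted(in_dir.iterdir()):
        if path.suffix.lower() not in (".png", ".tif", ".tiff", ".dcm", ".dicom"):
            continue
        for knee in preprocess_image(read_image(path, side=side), clahe=clahe):
            tag = "L" if knee.side == "left" else "R"
            out = out_dir / f"{knee.source_id}_{tag}.png"
            write_png(knee, out)
            written.append(out)
    return written
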