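"""The :class:`KneeImage` container and radiograph readers/writers.

Every stage of the pipeline passes :class:`KneeImage` objects: a 2-D grayscale
raster plus the metadata the preprocessing contracts need (bit depth, polarity,
anatomical side, provenance id). Coordinates everywhere in the package are
0-based, origin top-left, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

POLARITIES = ("dark_background", "bright_background", "unknown")
SIDES = ("left", "right", "double")


class InvalidImageError(ValueError):
    """Raised when pixel data violates the image contract (empty, not 2-D)."""


@dataclass
class KneeImage:
    pixels: np.ndarray
    bit_depth: int = 8
    polarity: str = "unknown"
    side: str = "double"
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvalidImageError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise InvalidImageError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.polarity not in POLARITIES:
            raise InvalidImageError(f"unknown polarity {self.polarity!r}")
        if self.side not in SIDES:
            raise InvalidImageError(f"unknown side {self.side!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_representable(self) -> int:
        return (1 << self.bit_depth) - 1

    def with_(self, **kwargs) -> "KneeImage":
        return replace(self, **kwargs)


def read_image(path: str | Path, side: str = "double") -> KneeImage:
    """Read a grayscale PNG/TIFF or single-frame monochrome DICOM.

    DICOM files with MONOCHROME1 photometric interpretation display low values
    as bright, i.e. a bright background; they are tagged accordingly so that
    polarity normalization inverts them.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path, side)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an (identical-channel) RGB export
        arr = arr[..., 0]
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return KneeImage(arr, bit_depth=bit_depth, polarity="unknown", side=side,
                     source_id=path.stem)


def _read_dicom(path: Path, side: str) -> KneeImage:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise InvalidImageError("only single-frame monochrome DICOM is supported")
    bits = int(getattr(ds, "BitsStored", 8 if arr.dtype.itemsize == 1 else 16))
    bit_depth = 8 if bits <= 8 else 16
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    polarity = "bright_background" if photometric == "MONOCHROME1" else "unknown"
    return KneeImage(arr, bit_depth=bit_depth, polarity=polarity, side=side,
                     source_id=path.stem)


def write_png(img: KneeImage, path: str | Path) -> None:
    if img.bit_depth != 8:
        raise InvalidImageError("only 8-bit images are written; standardize first")
    iio.imwrite(Path(path), img.pixels.astype(np.uint8))
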