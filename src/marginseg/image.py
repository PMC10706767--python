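"""In-memory containers and file I/O for ultrasound images, masks and maps.

Images are plain 2-D float arrays in [0, 1] carried in a small dataclass
together with their physical pixel spacing (mm/px per axis) and provenance
labels. Masks travel as binary arrays and are stored on disk as 0/255
single-channel PNG; probability maps are stored as 32-bit float TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

# Philips L15-7io: 3 cm imaging depth over 344 raw rows.
RAW_SHAPE = (344, 430)  # rows x cols of the acquisition
RAW_ROW_SPACING_MM = 30.0 / 344  # ~0.0872 mm/px
RAW_COL_SPACING_MM = 30.0 / 344  # square pixels assumed at acquisition
# After crop-to-top-half (172 rows) and resize to 128 x 128.
DEFAULT_ROW_SPACING_MM = RAW_ROW_SPACING_MM * 172 / 128  # ~0.1172 mm/px
DEFAULT_COL_SPACING_MM = RAW_COL_SPACING_MM * 430 / 128  # ~0.293 mm/px


@dataclass
class USImage:
    """A 2-D grayscale B-mode image in [0, 1] with physical pixel spacing.

    Row index increases with depth: row 0 is the transducer surface, which
    in intra-operative specimen imaging is the resection plane.
    """

    pixels: np.ndarray
    row_spacing_mm: float = DEFAULT_ROW_SPACING_MM
    col_spacing_mm: float = DEFAULT_COL_SPACING_MM
    patient_id: str = ""
    image_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("USImage pixels must be 2-D")
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **changes) -> "USImage":
        return replace(self, pixels=pixels, **changes)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF and scale it to float [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask as a binary uint8 array."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), ((np.asarray(mask) > 0) * 255).astype(np.uint8))


def read_probability_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_probability_map(path: str | Path, probs: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(probs, dtype=np.float32))


def write_weight_field(path: str | Path, field_: np.ndarray) -> None:
    """Persist a per-pixel weight field as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(field_, dtype=np.float32))
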