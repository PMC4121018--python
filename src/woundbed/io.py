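"""Image input/output and impulse-noise suppression.

Wound photographs arrive as 8-bit RGB rasters (PNG/JPEG/TIFF) shot with
consumer cameras; rapid photography and lens dust leave salt-and-pepper
impulses that a per-channel median filter removes while preserving the
wound-boundary edges the segmentation stage depends on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

log = logging.getLogger(__name__)

MIN_SIDE = 16  # pipeline minimum image side


class InputError(ValueError):
    """Raised for unreadable or structurally invalid input files."""


@dataclass
class RgbImage:
    """An 8-bit three-plane photograph.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3), dtype uint8
    id : source identifier (typically the file stem)
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {p.shape}")
        if p.shape[0] < MIN_SIDE or p.shape[1] < MIN_SIDE:
            raise ValueError(
                f"image {p.shape[0]}x{p.shape[1]} below pipeline minimum {MIN_SIDE}"
            )
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise ValueError("intensities outside [0, 255]")
            p = p.astype(np.uint8)
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Boolean mask with the same height/width as the image it annotates."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


def read_image(path: str | Path) -> RgbImage:
    """Read an image file as an :class:`RgbImage`.

    Grayscale inputs are replicated to three planes; an alpha plane is
    dropped.  Non-8-bit depths are linearly rescaled to [0, 255] with a
    warning (consumer-camera sources vary).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except Exception as exc:  # PIL raises a zoo of types for bad files
        raise InputError(f"cannot read image file {path}: {exc}") from exc

    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"{path}: unsupported raster layout {arr.shape}")

    if arr.dtype != np.uint8:
        warnings.warn(
            f"{path.name}: non-8-bit depth ({arr.dtype}); rescaling to [0, 255]",
            stacklevel=2,
        )
        arr = arr.astype(np.float64)
        hi = arr.max()
        if hi > 0:
            arr = arr * (255.0 / hi)
        arr = np.round(arr).astype(np.uint8)

    return RgbImage(pixels=arr, id=path.stem)


def write_image(img: RgbImage, path: str | Path) -> None:
    Image.fromarray(img.pixels, mode="RGB").save(Path(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a single-channel PNG with values {0, 255}."""
    Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L").save(Path(path))


def read_mask(path: str | Path) -> BinaryMask:
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return BinaryMask(pixels=arr >= 128, image_id=Path(path).stem)


def median_filter_rgb(img: RgbImage, window: int = 5) -> RgbImage:
    """Median-filter each RGB channel independently with a square window.

    Borders are handled by edge replication so the filter does not invent
    dark rims that would bias downstream saturation statistics.

    Parameters
    ----------
    window : odd int >= 3, side of the square neighborhood (default 5).
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    out = np.empty_like(img.pixels)
    for c in range(3):
        out[:, :, c] = ndimage.median_filter(
            img.pixels[:, :, c], size=window, mode="nearest"
        )
    return RgbImage(pixels=out, id=img.id)
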