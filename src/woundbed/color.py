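"""Color-space conversions: 15 spaces, 45 scalar channels.

The tissue descriptor quantifies color in fifteen spaces (RGB, HSI, XYZ,
Lab, Luv, LCH, HSV, HSL, YUV, YIQ, CAT02-LMS, YCbCr, JPEG-YCbCr, YDbDr,
YPbPr), three components each.  Segmentation uses only the HSI saturation
plane: saturation measures how far a color sits from the gray axis, and a
wound bed against skin separates far better there than in any raw RGB
plane.

Conventions (consumer-camera defaults): sRGB primaries with D65 white
point for the CIE family; ITU-R BT.601 for the video/luma family; the
JPEG variant of YCbCr is the full-range JFIF transform.  Most transforms
are delegated to :mod:`skimage.color`; HSI, HSL, CAT02-LMS and JPEG-YCbCr
are implemented here.  Each channel carries a declared numeric range used
wherever an operation needs 8-bit quantization; features otherwise see
the channel in its native range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import color as skcolor

from .io import RgbImage

__all__ = [
    "ChannelId",
    "ChannelImage",
    "CHANNEL_IDS",
    "N_CHANNELS",
    "to_hsi",
    "s_channel_8bit",
    "convert_all_spaces",
    "channel_manifest",
    "write_manifest",
]


@dataclass(frozen=True)
class ChannelId:
    """Identity of one scalar color plane: space, component index and name."""

    space: str
    component: int
    name: str
    lo: float
    hi: float

    @property
    def key(self) -> str:
        return f"{self.space}:{self.name}"


@dataclass
class ChannelImage:
    """One scalar plane from one color-space component."""

    pixels: np.ndarray
    id: ChannelId

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("channel plane must be 2-D")


def _rgb_f(img: RgbImage) -> np.ndarray:
    return img.pixels.astype(np.float64) / 255.0


def _hsi_planes(img: RgbImage) -> np.ndarray:
    """Geometric HSI: H in degrees [0, 360), S in [0, 1], I in [0, 255]."""
    rgb = img.pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    i = total / 3.0

    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / np.where(total > 0, total, 1.0), 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cosang = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    h = np.where(b > g, 360.0 - theta, theta)
    h = np.where(den > 0, h, 0.0)  # achromatic: hue undefined -> 0
    h = np.where(h >= 360.0, 0.0, h)
    return np.stack([h, np.clip(s, 0.0, 1.0), i], axis=-1)


def _hsl_planes(img: RgbImage) -> np.ndarray:
    """HSL with all components in [0, 1] (hue as a fraction of the circle)."""
    rgb = _rgb_f(img)
    mx = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    l = (mx + mn) / 2.0
    c = mx - mn
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(c > 0, c / (1.0 - np.abs(2.0 * l - 1.0)), 0.0)
    # hue identical to HSV's hexagonal hue
    hsv = skcolor.rgb2hsv(rgb)
    h = np.where(c > 0, hsv[..., 0], 0.0)
    return np.stack([h, np.clip(s, 0.0, 1.0), l], axis=-1)


# CAT02 chromatic-adaptation matrix (CIECAM02), applied to XYZ.
_CAT02 = np.array(
    [
        [0.7328, 0.4286, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)


def _cat02_lms_planes(img: RgbImage) -> np.ndarray:
    xyz = skcolor.rgb2xyz(_rgb_f(img))
    return xyz @ _CAT02.T


def _jpeg_ycbcr_planes(img: RgbImage) -> np.ndarray:
    """Full-range JFIF YCbCr on the 0..255 scale."""
    rgb = img.pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return np.stack([y, cb, cr], axis=-1)


def _lch_planes(img: RgbImage) -> np.ndarray:
    return skcolor.lab2lch(skcolor.rgb2lab(_rgb_f(img)))


# (space, component names, converter, per-component (lo, hi) declared ranges)
_SPACES: list[tuple[str, tuple[str, str, str], object, tuple[tuple[float, float], ...]]] = [
    ("RGB", ("R", "G", "B"), lambda im: im.pixels.astype(np.float64),
     ((0, 255), (0, 255), (0, 255))),
    ("HSI", ("H", "S", "I"), _hsi_planes,
     ((0, 360), (0, 1), (0, 255))),
    ("XYZ", ("X", "Y", "Z"), lambda im: skcolor.rgb2xyz(_rgb_f(im)),
     ((0, 0.9505), (0, 1.0), (0, 1.089))),
    ("Lab", ("L", "a", "b"), lambda im: skcolor.rgb2lab(_rgb_f(im)),
     ((0, 100), (-110, 110), (-110, 110))),
    ("Luv", ("L", "u", "v"), lambda im: skcolor.rgb2luv(_rgb_f(im)),
     ((0, 100), (-140, 180), (-140, 125))),
    ("LCH", ("L", "C", "H"), _lch_planes,
     ((0, 100), (0, 135), (0, 2 * np.pi))),
    ("HSV", ("H", "S", "V"), lambda im: skcolor.rgb2hsv(_rgb_f(im)),
     ((0, 1), (0, 1), (0, 1))),
    ("HSL", ("H", "S", "L"), _hsl_planes,
     ((0, 1), (0, 1), (0, 1))),
    ("YUV", ("Y", "U", "V"), lambda im: skcolor.rgb2yuv(_rgb_f(im)),
     ((0, 1), (-0.437, 0.437), (-0.616, 0.616))),
    ("YIQ", ("Y", "I", "Q"), lambda im: skcolor.rgb2yiq(_rgb_f(im)),
     ((0, 1), (-0.596, 0.596), (-0.523, 0.523))),
    ("CAT02-LMS", ("L", "M", "S"), _cat02_lms_planes,
     ((-0.18, 1.13), (-0.67, 1.71), (0, 1.09))),
    ("YCbCr", ("Y", "Cb", "Cr"), lambda im: skcolor.rgb2ycbcr(_rgb_f(im)),
     ((16, 235), (16, 240), (16, 240))),
    ("JPEG-YCbCr", ("Y", "Cb", "Cr"), _jpeg_ycbcr_planes,
     ((0, 255), (0, 255), (0, 255))),
    ("YDbDr", ("Y", "Db", "Dr"), lambda im: skcolor.rgb2ydbdr(_rgb_f(im)),
     ((0, 1), (-1.334, 1.334), (-1.334, 1.334))),
    ("YPbPr", ("Y", "Pb", "Pr"), lambda im: skcolor.rgb2ypbpr(_rgb_f(im)),
     ((0, 1), (-0.5, 0.5), (-0.5, 0.5))),
]

CHANNEL_IDS: tuple[ChannelId, ...] = tuple(
    ChannelId(space, k, names[k], float(rng[k][0]), float(rng[k][1]))
    for space, names, _conv, rng in _SPACES
    for k in range(3)
)
N_CHANNELS = len(CHANNEL_IDS)
assert N_CHANNELS == 45


def to_hsi(img: RgbImage) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Convert to geometric HSI and return the (H, S, I) planes.

    I = (R+G+B)/3 on the 0..255 scale; S = 1 - 3*min(R,G,B)/(R+G+B) with
    S = 0 for black pixels; H from the arccos form, in degrees [0, 360),
    with H = 0 at achromatic pixels.
    """
    planes = _hsi_planes(img)
    ids = CHANNEL_IDS[3:6]
    return tuple(ChannelImage(planes[..., k], ids[k]) for k in range(3))  # type: ignore[return-value]


def s_channel_8bit(img: RgbImage) -> ChannelImage:
    """The saturation plane scaled from [0, 1] to [0, 255] (real-valued)."""
    _, s, _ = to_hsi(img)
    cid = ChannelId("HSI", 1, "S8", 0.0, 255.0)
    return ChannelImage(s.pixels * 255.0, cid)


def convert_all_spaces(img: RgbImage) -> list[ChannelImage]:
    """All 45 channel planes, in the fixed :data:`CHANNEL_IDS` order."""
    out: list[ChannelImage] = []
    i = 0
    for _space, _names, conv, _rng in _SPACES:
        planes = conv(img)
        for k in range(3):
            out.append(ChannelImage(planes[..., k], CHANNEL_IDS[i]))
            i += 1
    return out


def channel_manifest() -> list[dict]:
    """Machine-readable description of the 45 channels, in order."""
    return [
        {"index": i, "space": c.space, "component": c.name,
         "lo": c.lo, "hi": c.hi}
        for i, c in enumerate(CHANNEL_IDS)
    ]


def write_manifest(path: str | Path) -> None:
    Path(path).write_text(json.dumps(channel_manifest(), indent=1))
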