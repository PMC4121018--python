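"""Color and texture descriptors for wound tissue regions.

Per color channel (45 of them) a region yields 15 features:

* five color moments — population mean, standard deviation, variance,
  skewness and kurtosis of the masked pixel values;
* Shannon entropy in bits over a 256-bin quantization of the channel;
* three local-contrast values (T - A)/(T + A), where T averages pixels at
  or above a central measure (mean / median / mode) and A averages the
  rest;
* mean rotation-invariant local binary pattern (LBP) and mean local
  variance (VAR) at radii R = 1, 2, 3 with P = 8, 16, 24 circular
  neighbors.

Totalling 675 entries in a fixed, documented order.  Texture neighborhoods
are sampled on a circle with bilinear interpolation and must lie entirely
inside the region mask, so background never contaminates tissue texture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .color import CHANNEL_IDS, ChannelImage, convert_all_spaces
from .io import BinaryMask, RgbImage

log = logging.getLogger(__name__)

LABELS = ("granulation", "slough", "necrotic")
MIN_REGION_PIXELS = 16

FEATURE_NAMES_PER_CHANNEL = (
    "mean", "std", "variance", "skewness", "kurtosis",
    "entropy", "lc_mean", "lc_median", "lc_mode",
    "lbp_r1", "lbp_r2", "lbp_r3", "var_r1", "var_r2", "var_r3",
)
N_FEATURES = len(CHANNEL_IDS) * len(FEATURE_NAMES_PER_CHANNEL)
assert N_FEATURES == 675

LBP_RADII = (1, 2, 3)  # with P = 8 * R neighbors

META_COLUMNS = ("image_id", "region_id", "label")


def feature_names() -> list[str]:
    """The 675 column names, channel-major: ``<space>_<component>_<feature>``."""
    return [
        f"{cid.space}_{cid.name}_{feat}"
        for cid in CHANNEL_IDS
        for feat in FEATURE_NAMES_PER_CHANNEL
    ]


@dataclass
class TissueRegion:
    """A labeled (or unlabeled) pixel region within one photograph."""

    image_id: str
    mask: BinaryMask
    label: str | None = None
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown tissue label {self.label!r}")
        if self.mask.area < MIN_REGION_PIXELS:
            raise ValueError(
                f"region has {self.mask.area} pixels; minimum is {MIN_REGION_PIXELS}"
            )


def color_moments(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """Population (1/N) mean, std, variance, skewness and kurtosis.

    Skewness and kurtosis are defined as 0 for a zero-variance sample so
    degenerate flat regions still produce finite features.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    mean = float(v.mean())
    var = float(((v - mean) ** 2).mean())
    std = float(np.sqrt(var))
    if std == 0.0:
        return mean, 0.0, 0.0, 0.0, 0.0
    z = (v - mean) / std
    skew = float((z**3).mean())
    kurt = float((z**4).mean())
    return mean, std, var, skew, kurt


def quantize256(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Quantize values into integer bins 0..255 over the declared range."""
    v = np.asarray(values, dtype=np.float64)
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.int64)
    scaled = (np.clip(v, lo, hi) - lo) / (hi - lo) * 256.0
    return np.clip(np.floor(scaled), 0, 255).astype(np.int64)


def shannon_entropy(values: np.ndarray, lo: float = 0.0, hi: float = 255.0) -> float:
    """Shannon entropy in bits of the 256-bin quantized value distribution."""
    q = quantize256(values, lo, hi)
    if q.size == 0:
        raise ValueError("empty region")
    counts = np.bincount(q.ravel(), minlength=256)
    p = counts[counts > 0] / q.size
    return float(-(p * np.log2(p)).sum())


def local_contrast(
    values: np.ndarray,
    center: str = "mean",
    lo: float = 0.0,
    hi: float = 255.0,
) -> float:
    """Contrast (T - A)/(T + A) around a central measure of the region.

    T averages pixels >= the central value, A averages pixels below it.
    Returns 0 when either side is empty or T + A == 0.  The mode central
    value is located on the 256-bin quantized histogram (smallest bin wins
    ties) and mapped back to the native scale at the bin center.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("local contrast needs at least 2 values")
    if center == "mean":
        c = v.mean()
    elif center == "median":
        c = float(np.median(v))
    elif center == "mode":
        q = quantize256(v, lo, hi)
        counts = np.bincount(q, minlength=256)
        mode_bin = int(np.argmax(counts))  # argmax takes the smallest on ties
        c = lo + (mode_bin + 0.5) * (hi - lo) / 256.0 if hi > lo else lo
    else:
        raise ValueError(f"unknown central measure {center!r}")
    above = v[v >= c]
    below = v[v < c]
    if above.size == 0 or below.size == 0:
        return 0.0
    t, a = above.mean(), below.mean()
    if t + a == 0.0:
        return 0.0
    return float((t - a) / (t + a))


def _ror_min(codes: np.ndarray, p: int) -> np.ndarray:
    """Minimum over all circular bit rotations of P-bit codes."""
    full = (1 << p) - 1
    best = codes.copy()
    for i in range(1, p):
        rot = ((codes >> i) | (codes << (p - i))) & full
        np.minimum(best, rot, out=best)
    return best


def lbp_ri_code(neighbors: np.ndarray, center: float) -> int:
    """Rotation-invariant LBP code of one circular neighborhood.

    Bits are s(g_p - g_c) with s(x) = 1 iff x >= 0, weighted 2^p; the
    returned code is the minimum over all P circular rotations.
    """
    g = np.asarray(neighbors, dtype=np.float64)
    p = g.size
    if p not in (8, 16, 24):
        raise ValueError(f"P must be 8, 16 or 24, got {p}")
    bits = (g >= center).astype(np.int64)
    code = int((bits << np.arange(p)).sum())
    return int(_ror_min(np.array([code]), p)[0])


def lbp_var_from_samples(
    samples: np.ndarray, centers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-invariant LBP codes and local variances for sampled neighborhoods.

    `samples` is (n, P) circular neighbor values, `centers` the n center
    values.  VAR is the population variance of each neighbor ring.
    """
    g = np.asarray(samples, dtype=np.float64)
    p = g.shape[1]
    # tiny slack absorbs bilinear round-off when a neighbor equals the center
    bits = (g >= np.asarray(centers, dtype=np.float64)[:, None] - 1e-9).astype(np.int64)
    codes = (bits << np.arange(p)).sum(axis=1)
    ri = _ror_min(codes, p)
    mu = g.mean(axis=1)
    var = ((g - mu[:, None]) ** 2).mean(axis=1)
    return ri, var


def _circular_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    p = 8 * radius
    ang = 2.0 * np.pi * np.arange(p) / p
    # neighbor p at angle 2*pi*p/P from the +x axis; rows grow downward
    return -radius * np.sin(ang), radius * np.cos(ang)


def lbp_var_maps(
    channel: ChannelImage | np.ndarray,
    mask: BinaryMask | np.ndarray,
    radius: int,
    lo: float | None = None,
    hi: float | None = None,
) -> tuple[float, float]:
    """Mean rotation-invariant LBP and mean local variance over a region.

    P = 8 * radius neighbors are sampled on a circle by bilinear
    interpolation of the 256-bin quantized channel.  Only pixels whose
    entire interpolation support lies inside the mask contribute.  Returns
    (0.0, 0.0) with a warning when no pixel qualifies.
    """
    if radius not in LBP_RADII:
        raise ValueError(f"radius must be one of {LBP_RADII}")
    if isinstance(channel, ChannelImage):
        plane = channel.pixels
        if lo is None:
            lo, hi = channel.id.lo, channel.id.hi
    else:
        plane = np.asarray(channel, dtype=np.float64)
        if lo is None:
            lo, hi = 0.0, 255.0
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    q = quantize256(plane, lo, hi).astype(np.float64)
    h, w = q.shape
    p_count = 8 * radius

    rows, cols = np.nonzero(m)
    if rows.size == 0:
        log.warning("lbp_var_maps: empty mask")
        return 0.0, 0.0
    dr, dc = _circular_offsets(radius)

    valid = np.ones(rows.size, dtype=bool)
    samples = np.empty((rows.size, p_count), dtype=np.float64)
    for p in range(p_count):
        ys = rows + dr[p]
        xs = cols + dc[p]
        y0 = np.floor(ys + 1e-9).astype(np.int64)
        x0 = np.floor(xs + 1e-9).astype(np.int64)
        wy = ys - y0
        wx = xs - x0
        wy[np.abs(wy) < 1e-9] = 0.0
        wx[np.abs(wx) < 1e-9] = 0.0
        # zero-weight corners are neither read nor required to be in-mask,
        # so axis-aligned (integer-offset) samples behave symmetrically
        need_y1 = wy > 0
        need_x1 = wx > 0
        inb = (
            (y0 >= 0) & (x0 >= 0)
            & (y0 + need_y1 < h) & (x0 + need_x1 < w)
        )
        y0c, x0c = np.clip(y0, 0, h - 1), np.clip(x0, 0, w - 1)
        y1c, x1c = np.clip(y0 + 1, 0, h - 1), np.clip(x0 + 1, 0, w - 1)
        corner_ok = (
            m[y0c, x0c]
            & (m[y0c, x1c] | ~need_x1)
            & (m[y1c, x0c] | ~need_y1)
            & (m[y1c, x1c] | ~(need_y1 & need_x1))
        )
        valid &= inb & corner_ok
        samples[:, p] = (
            q[y0c, x0c] * (1 - wy) * (1 - wx)
            + q[y0c, x1c] * (1 - wy) * wx
            + q[y1c, x0c] * wy * (1 - wx)
            + q[y1c, x1c] * wy * wx
        )

    if not valid.any():
        log.warning("lbp_var_maps: no pixel has a full in-mask neighborhood (R=%d)", radius)
        return 0.0, 0.0

    ri, var = lbp_var_from_samples(samples[valid], q[rows[valid], cols[valid]])
    return float(ri.mean()), float(var.mean())


def channel_features(channel: ChannelImage, mask: BinaryMask) -> list[float]:
    """The 15 per-channel features, in :data:`FEATURE_NAMES_PER_CHANNEL` order."""
    vals = channel.pixels[mask.pixels]
    lo, hi = channel.id.lo, channel.id.hi
    mean, std, var, skew, kurt = color_moments(vals)
    ent = shannon_entropy(vals, lo, hi)
    lcs = [local_contrast(vals, c, lo, hi) for c in ("mean", "median", "mode")]
    lbps, vars_ = [], []
    for r in LBP_RADII:
        l, v = lbp_var_maps(channel, mask, r)
        lbps.append(l)
        vars_.append(v)
    return [mean, std, var, skew, kurt, ent, *lcs, *lbps, *vars_]


def extract_features(
    img: RgbImage,
    region: TissueRegion,
    channels: list[ChannelImage] | None = None,
) -> np.ndarray:
    """The full 675-entry descriptor for one region of one photograph.

    Pass precomputed `channels` (from :func:`convert_all_spaces`) to reuse
    conversions across regions of the same image.
    """
    if region.mask.shape != img.shape:
        raise ValueError("region mask does not match image shape")
    if channels is None:
        channels = convert_all_spaces(img)
    out: list[float] = []
    for ch in channels:
        out.extend(channel_features(ch, region.mask))
    vec = np.asarray(out, dtype=np.float64)
    if not np.all(np.isfinite(vec)):
        bad = [feature_names()[i] for i in np.nonzero(~np.isfinite(vec))[0][:5]]
        raise AssertionError(f"non-finite features: {bad}")
    return vec


def build_feature_table(
    images: dict[str, RgbImage], regions: list[TissueRegion]
) -> pd.DataFrame:
    """Feature rows for every region; channels converted once per image."""
    cache: dict[str, list[ChannelImage]] = {}
    rows = []
    names = feature_names()
    for reg in regions:
        img = images[reg.image_id]
        if reg.image_id not in cache:
            cache[reg.image_id] = convert_all_spaces(img)
        vec = extract_features(img, reg, channels=cache[reg.image_id])
        row = {"image_id": reg.image_id, "region_id": reg.region_id,
               "label": reg.label if reg.label is not None else ""}
        row.update(zip(names, vec))
        rows.append(row)
    return pd.DataFrame(rows, columns=[*META_COLUMNS, *names])


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), keep_default_na=False,
                     dtype={c: str for c in META_COLUMNS},
                     float_precision="round_trip")
    expected = [*META_COLUMNS, *feature_names()]
    if list(df.columns) != expected:
        raise ValueError("feature CSV columns do not match the manifest")
    return df
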