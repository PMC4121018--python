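"""Wound-bed segmentation by fuzzy-divergence threshold minimization.

A gray-level threshold t splits the saturation plane into a candidate
object (wound, high saturation) and background (skin).  Each pixel gets a
Gaussian membership grade expressing how typical it is of its own region:
mu(f) = exp(-(f - m_r)^2 / (2 sigma^2)) where m_r is the region's mean
gray value and sigma is half the channel's dynamic range.  The exponential
fuzzy divergence between that membership image and an ideally segmented
image (membership 1 everywhere) measures the residual edge ambiguity of
the split; the threshold minimizing it over the full 1..255 scan is
selected.  The raw mask is then regularized morphologically.

The divergence between membership images A and B sums, over pixels,

    2 - (1 - mu_A + mu_B) e^(mu_A - mu_B) - (1 - mu_B + mu_A) e^(mu_B - mu_A)

which is symmetric, zero iff mu_A == mu_B, and non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .color import ChannelImage
from .io import BinaryMask, RgbImage

log = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Degenerate input or empty result at a segmentation stage."""


@dataclass
class SegmentationResult:
    threshold: int
    divergence: float
    raw_mask: BinaryMask
    refined_mask: BinaryMask


def _as_plane(channel: ChannelImage | np.ndarray) -> np.ndarray:
    if isinstance(channel, ChannelImage):
        return channel.pixels
    return np.asarray(channel, dtype=np.float64)


def gaussian_membership(
    channel: ChannelImage | np.ndarray, threshold: int
) -> np.ndarray:
    """Gaussian membership map for the object/background split at `threshold`.

    Pixels >= threshold form the object region; each pixel's membership is
    exp(-(f - m_r)^2 / (2 sigma^2)) with m_r its region's mean gray value
    and sigma = (max - min) / 2 of the channel, floored at 1.  An empty
    region contributes nothing (it has no pixels).  A constant channel
    yields membership 1 everywhere.
    """
    f = _as_plane(channel)
    if not 1 <= threshold <= 255:
        raise ValueError(f"threshold must be in [1, 255], got {threshold}")
    sigma = max((f.max() - f.min()) / 2.0, 1.0)
    obj = f >= threshold
    mu = np.empty_like(f)
    for region in (obj, ~obj):
        if region.any():
            m_r = f[region].mean()
            mu[region] = np.exp(-((f[region] - m_r) ** 2) / (2.0 * sigma**2))
    return mu


def fuzzy_divergence(a: np.ndarray, b: np.ndarray) -> float:
    """Total exponential fuzzy divergence between two membership maps."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    terms = 2.0 - (1.0 - d) * np.exp(d) - (1.0 + d) * np.exp(-d)
    return float(terms.sum())


def _divergence_to_ideal_by_gray(hist: np.ndarray, threshold: int, sigma: float) -> float:
    """D(membership(t), ones) computed per gray level from the histogram.

    Membership depends only on the gray value once the split is fixed, so
    the pixel sum collapses onto the 256-bin histogram.  This is an exact
    rewrite of the per-pixel sum, not an approximation.
    """
    g = np.arange(256, dtype=np.float64)
    counts = hist.astype(np.float64)
    total = 0.0
    for region in (g >= threshold, g < threshold):
        n = counts[region].sum()
        if n == 0:
            continue
        m_r = (g[region] * counts[region]).sum() / n
        mu = np.exp(-((g[region] - m_r) ** 2) / (2.0 * sigma**2))
        d = mu - 1.0
        per_level = 2.0 - (1.0 - d) * np.exp(d) - (1.0 + d) * np.exp(-d)
        total += (counts[region] * per_level).sum()
    return float(total)


def select_threshold(
    channel: ChannelImage | np.ndarray,
    refine: bool = True,
    selem_radius: int | None = None,
) -> SegmentationResult:
    """Exhaustive 1..255 threshold scan minimizing divergence to the ideal image.

    The channel is quantized to 8 bits for the scan.  Ties break toward the
    smallest threshold.  Raises :class:`SegmentationError` on a constant
    (degenerate) channel.
    """
    f = _as_plane(channel)
    q = np.clip(np.round(f), 0, 255).astype(np.uint8)
    if q.min() == q.max():
        raise SegmentationError("degenerate image: constant channel, no valid threshold")

    hist = np.bincount(q.ravel(), minlength=256)
    sigma = max((float(q.max()) - float(q.min())) / 2.0, 1.0)
    divergences = np.array(
        [_divergence_to_ideal_by_gray(hist, t, sigma) for t in range(1, 256)]
    )
    best = int(np.argmin(divergences))  # first minimum -> smallest threshold
    t_star = best + 1
    raw = BinaryMask(q >= t_star)
    refined = refine_mask(raw, selem_radius=selem_radius) if refine else raw
    log.info("threshold %d selected, divergence %.4f", t_star, divergences[best])
    return SegmentationResult(
        threshold=t_star,
        divergence=float(divergences[best]),
        raw_mask=raw,
        refined_mask=refined,
    )


def default_selem_radius(shape: tuple[int, int]) -> int:
    """Disk radius for morphology, scaled to image size (3 at ~512 px side)."""
    return max(1, round(3 * min(shape) / 512))


def refine_mask(raw: BinaryMask, selem_radius: int | None = None) -> BinaryMask:
    """Morphological cleanup: closing, opening, hole fill, largest component.

    Uses a disk structuring element (radius scaled to image size unless
    given) and 8-connectivity.  Raises :class:`SegmentationError` if
    nothing survives.
    """
    if not raw.pixels.any():
        raise SegmentationError("no wound region found: empty raw mask")
    r = selem_radius if selem_radius is not None else default_selem_radius(raw.shape)
    selem = morphology.disk(r)
    m = morphology.closing(raw.pixels, selem)
    m = morphology.opening(m, selem)
    m = ndimage.binary_fill_holes(m)
    if not m.any():
        raise SegmentationError("no wound region found after refinement")
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(m, image_id=raw.image_id)


@dataclass
class CroppedWound:
    """Wound bed cut out of the photograph: bounding-box crop plus mask.

    Pixels outside the mask are zeroed as a sentinel and must be excluded
    from all downstream statistics via `mask`.
    """

    image: RgbImage
    mask: BinaryMask
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open


def crop_wound(img: RgbImage, mask: BinaryMask) -> CroppedWound:
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.pixels.any():
        raise SegmentationError("no wound region found: empty mask")
    rows = np.flatnonzero(mask.pixels.any(axis=1))
    cols = np.flatnonzero(mask.pixels.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    # keep the pipeline-minimum image size by padding the box if needed
    r1 = max(r1, min(r0 + 16, img.shape[0]))
    r0 = min(r0, max(0, r1 - 16))
    c1 = max(c1, min(c0 + 16, img.shape[1]))
    c0 = min(c0, max(0, c1 - 16))
    sub_mask = mask.pixels[r0:r1, c0:c1]
    sub_img = img.pixels[r0:r1, c0:c1].copy()
    sub_img[~sub_mask] = 0
    return CroppedWound(
        image=RgbImage(sub_img, id=img.id),
        mask=BinaryMask(sub_mask, image_id=img.id),
        bbox=(r0, r1, c0, c1),
    )


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    pa = a.pixels if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    pb = b.pixels if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pa, pb).sum() / denom)
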