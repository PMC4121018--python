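"""Synthetic wound photographs with ground truth.

Real chronic-wound corpora are clinical data and cannot ship with a code
package, so every pipeline stage is exercised on generated fixtures: a
skin-toned background with an embedded elliptical wound bed partitioned
into contiguous angular sectors of granulation (red), slough (yellow) and
necrotic (black) tissue, plus per-tissue ground-truth masks.  Gaussian
color jitter and a sinusoidal brightness ripple give the tissues
non-trivial texture; image-wide salt-and-pepper impulses emulate the
camera noise the median filter is there to remove.

Benchmark tissue fractions are drawn around the corpus composition the
classifier is meant to face (granulation/slough/necrotic roughly
0.29/0.59/0.12 by region count), with the necrotic share kept within
[0.06, 0.14]: necrotic eschar rendered as a neutral black is *less*
saturated than skin, so a saturation threshold cannot claim it, and
wounds dominated by eschar are outside what this segmentation method can
delineate (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import LABELS, MIN_REGION_PIXELS, TissueRegion
from .io import BinaryMask, RgbImage

DEFAULT_SKIN = (225, 190, 160)
DEFAULT_TISSUE_COLORS = {
    "granulation": (180, 40, 50),
    "slough": (200, 180, 80),
    "necrotic": (30, 25, 25),
}


@dataclass
class WoundSpec:
    """Full description of one synthetic wound photograph."""

    size: tuple[int, int] = (128, 128)          # (height, width)
    skin_color: tuple[int, int, int] = DEFAULT_SKIN
    center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    axes: tuple[float, float] = (38.0, 27.0)    # semi-axes (a, b), pixels
    rotation: float = 0.0                       # radians
    fractions: tuple[float, float, float] = (0.29, 0.59, 0.12)
    tissue_colors: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_COLORS))
    jitter_sigma: float = 8.0                   # per-channel Gaussian color noise
    impulse_fraction: float = 0.02              # salt-and-pepper pixel share
    texture_amplitude: float = 6.0              # sinusoidal brightness ripple
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=np.float64)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("tissue fractions must be non-negative and sum to 1")
        h, w = self.size
        a, b = self.axes
        r = self.rotation
        ext_c = np.hypot(a * np.cos(r), b * np.sin(r))
        ext_r = np.hypot(a * np.sin(r), b * np.cos(r))
        cr, cc = self.center
        if not (ext_r <= cr <= h - 1 - ext_r and ext_c <= cc <= w - 1 - ext_c):
            raise ValueError("infeasible geometry: wound ellipse exceeds the image")


@dataclass
class SyntheticWound:
    image: RgbImage
    wound_mask: BinaryMask
    tissue_masks: dict[str, BinaryMask]
    regions: list[TissueRegion]
    spec: WoundSpec


def generate(spec: WoundSpec) -> SyntheticWound:
    """Render the wound described by `spec`; bit-identical for a fixed seed.

    Tissue masks are pairwise disjoint, union to the wound ellipse, and
    match the requested fractions exactly by pixel count (pixels are dealt
    to sectors in angular order).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.skin_color

    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - spec.center[0]
    dx = cc - spec.center[1]
    r = spec.rotation
    u = (dx * np.cos(r) + dy * np.sin(r)) / spec.axes[0]
    v = (-dx * np.sin(r) + dy * np.cos(r)) / spec.axes[1]
    wound = u**2 + v**2 <= 1.0
    n_wound = int(wound.sum())
    if n_wound < MIN_REGION_PIXELS:
        raise ValueError("infeasible geometry: wound ellipse too small")

    # deal wound pixels to contiguous angular sectors in fraction proportion
    ys, xs = np.nonzero(wound)
    phi0 = rng.uniform(0, 2 * np.pi)
    ang = (np.arctan2(ys - spec.center[0], xs - spec.center[1]) - phi0) % (2 * np.pi)
    order = np.argsort(ang, kind="stable")
    counts = np.floor(np.asarray(spec.fractions) * n_wound).astype(int)
    for i in np.argsort(counts)[::-1][: n_wound - counts.sum()]:
        counts[i] += 1  # distribute the remainder to the largest sectors

    tissue_masks: dict[str, BinaryMask] = {}
    start = 0
    for label, count in zip(LABELS, counts):
        m = np.zeros((h, w), dtype=bool)
        sel = order[start : start + count]
        m[ys[sel], xs[sel]] = True
        start += count
        tissue_masks[label] = BinaryMask(m)
        if count == 0:
            continue
        color = np.asarray(spec.tissue_colors[label], dtype=np.float64)
        img[m] = color
        if spec.texture_amplitude > 0:
            fy, fx = rng.uniform(0.04, 0.15, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            ripple = spec.texture_amplitude * np.sin(
                2 * np.pi * (fy * ys[sel] + fx * xs[sel]) + phase
            )
            img[ys[sel], xs[sel]] += ripple[:, None]
        if spec.jitter_sigma > 0:
            img[ys[sel], xs[sel]] += rng.normal(0, spec.jitter_sigma, size=(count, 3))

    if spec.impulse_fraction > 0:
        k = int(round(spec.impulse_fraction * h * w))
        if k > 0:
            flat = rng.choice(h * w, size=k, replace=False)
            vals = rng.choice([0.0, 255.0], size=k)
            img.reshape(-1, 3)[flat] = vals[:, None]

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image_id = f"synthetic-{spec.seed}"
    image = RgbImage(pixels, id=image_id)
    regions = [
        TissueRegion(
            image_id=image_id,
            mask=tissue_masks[label],
            label=label,
            region_id=f"{image_id}:{label}",
        )
        for label in LABELS
        if tissue_masks[label].area >= MIN_REGION_PIXELS
    ]
    return SyntheticWound(
        image=image,
        wound_mask=BinaryMask(wound, image_id=image_id),
        tissue_masks=tissue_masks,
        regions=regions,
        spec=spec,
    )


def _benchmark_fractions(rng: np.random.Generator) -> tuple[float, float, float]:
    """Fractions around the corpus composition; necrotic share in [0.06, 0.14]."""
    base = np.array([0.29, 0.59, 0.12])
    f = rng.dirichlet(50.0 * base)
    nec = float(np.clip(f[2], 0.06, 0.14))
    rest = f[:2] / f[:2].sum() * (1.0 - nec)
    return float(rest[0]), float(rest[1]), nec


def make_benchmark(n_images: int, seed: int = 0, size: int = 128) -> list[SyntheticWound]:
    """A reproducible suite of wounds with randomized geometry and fractions."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    suite: list[SyntheticWound] = []
    for _ in range(n_images):
        a = rng.uniform(0.22, 0.30) * size
        b = rng.uniform(0.16, 0.24) * size
        rot = rng.uniform(0, np.pi)
        ext = max(np.hypot(a * np.cos(rot), b * np.sin(rot)),
                  np.hypot(a * np.sin(rot), b * np.cos(rot)))
        lo, hi = ext + 2, size - 3 - ext
        spec = WoundSpec(
            size=(size, size),
            center=(rng.uniform(lo, hi), rng.uniform(lo, hi)),
            axes=(a, b),
            rotation=rot,
            fractions=_benchmark_fractions(rng),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        suite.append(generate(spec))
    return suite
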