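"""Synthetic data generators: pseudo-slides and witness feature bags.

Both generators ship the latent ground truth needed to score the rest of the
pipeline (true tissue masks and blob geometry for slides; witness index sets
and the planted direction for bags), and both are pure functions of their
spec + seed.

``make_slide`` emulates the geometry of an H&E scan — bright glass
(~230 +/- 10 gray), dark elliptical tissue blobs with a pink/purple tint,
optionally a saturated pen stroke — rendered at full resolution and
downsampled into a 3-level pyramid by block averaging.

``make_bags`` is the classic MIL witness construction: instances are standard
normal vectors in d dimensions; positive bags additionally contain a few
"witness" instances whose mean is shifted by ``shift`` background standard
deviations along one fixed random unit direction. Only those few instances
carry the label signal, which is exactly the weak-supervision regime
slide-level molecular labels create: a handful of patches carry the evidence
and nothing marks which ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .mil import Bag
from .slide_io import (SlideHandle, block_mean_downsample, open_slide,
                       register_memory_slide, write_pyramid_tiff)

__all__ = [
    "SlideSpec",
    "BagSpec",
    "make_slide",
    "make_slide_tiff",
    "make_bags",
    "make_texture_patches",
    "STANDARD_BENCHMARK",
]


@dataclass(frozen=True)
class SlideSpec:
    """Geometry and appearance of a synthetic pyramidal slide.

    `blobs` fixes ellipses explicitly as (cx, cy, rx, ry) in level-0 pixels;
    when None, `n_blobs` ellipses are placed at random (seeded). The optional
    `texture_signal` adds a sinusoidal intensity modulation of the given
    spatial frequency inside a (x0, y0, x1, y1) region, giving downstream
    encoders a label-correlated texture to pick up.
    """

    width: int = 1024
    height: int = 1024
    n_blobs: int = 3
    blobs: tuple[tuple[int, int, int, int], ...] | None = None
    blob_intensity: tuple[int, int] = (100, 150)
    pen_mark: bool = False
    texture_signal: dict | None = None
    n_levels: int = 3
    seed: int = 0


def _render_level0(spec: SlideSpec) -> tuple[np.ndarray, np.ndarray, list]:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    glass = 230.0 + rng.normal(0.0, 10.0, (h, w))
    img = np.stack([glass, glass, glass], axis=-1)
    img += rng.normal(0.0, 2.0, img.shape)  # slight per-channel scanner noise

    if spec.blobs is not None:
        blobs = [tuple(b) for b in spec.blobs]
    else:
        blobs = []
        for _ in range(spec.n_blobs):
            rx = int(rng.integers(w // 10, w // 5))
            ry = int(rng.integers(h // 10, h // 5))
            cx = int(rng.integers(rx, w - rx))
            cy = int(rng.integers(ry, h - ry))
            blobs.append((cx, cy, rx, ry))

    for (cx, cy, rx, ry) in blobs:
        if cx - rx < 0 or cx + rx > w or cy - ry < 0 or cy + ry > h:
            raise ParameterError(f"blob {(cx, cy, rx, ry)} exceeds slide bounds")

    yy, xx = np.mgrid[0:h, 0:w]
    tissue = np.zeros((h, w), dtype=bool)
    lo, hi = spec.blob_intensity
    for (cx, cy, rx, ry) in blobs:
        inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        tissue |= inside
        base = rng.uniform(lo, hi)
        intensity = base + rng.normal(0.0, 6.0, (h, w))
        if spec.texture_signal is not None:
            x0, y0, x1, y1 = spec.texture_signal["region"]
            freq = spec.texture_signal["frequency"]
            region = (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)
            intensity = np.where(region,
                                 intensity + 25.0 * np.sin(2 * np.pi * freq * xx)
                                 * np.sin(2 * np.pi * freq * yy),
                                 intensity)
        # pink/purple H&E-like tint: red/blue above the base gray, green below
        img[..., 0] = np.where(inside, intensity * 1.15, img[..., 0])
        img[..., 1] = np.where(inside, intensity * 0.75, img[..., 1])
        img[..., 2] = np.where(inside, intensity * 1.05, img[..., 2])

    if spec.pen_mark:
        # saturated green stroke along the left edge, over glass
        x0, x1 = w // 32, w // 32 + max(8, w // 64)
        img[h // 8: 7 * h // 8, x0:x1, 0] = 40.0
        img[h // 8: 7 * h // 8, x0:x1, 1] = 160.0
        img[h // 8: 7 * h // 8, x0:x1, 2] = 60.0

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, tissue, blobs


def _pyramid(level0: np.ndarray, n_levels: int) -> list[np.ndarray]:
    levels = [level0]
    for _ in range(n_levels - 1):
        levels.append(block_mean_downsample(levels[-1], 2))
    return levels


def _mask_pyramid(mask0: np.ndarray, n_levels: int) -> list[np.ndarray]:
    masks = [mask0]
    for _ in range(n_levels - 1):
        m = masks[-1].astype(np.float64)
        h, w = m.shape[0] // 2, m.shape[1] // 2
        m = m[: h * 2, : w * 2].reshape(h, 2, w, 2).mean(axis=(1, 3))
        masks.append(m >= 0.5)
    return masks


def make_slide(spec: SlideSpec = SlideSpec()) -> tuple[SlideHandle, dict]:
    """Render a synthetic pyramidal slide into the in-memory backend.

    Returns (handle, ground_truth) where ground_truth holds 'tissue_masks'
    (one bool array per level), 'blobs' (ellipse parameters) and 'levels'
    (the rendered pixel arrays, finest first).
    """
    level0, tissue, blobs = _render_level0(spec)
    levels = _pyramid(level0, spec.n_levels)
    masks = _mask_pyramid(tissue, spec.n_levels)
    key = (f"slide-s{spec.seed}-{spec.width}x{spec.height}-b{len(blobs)}"
           f"-p{int(spec.pen_mark)}")
    path = register_memory_slide(key, levels)
    handle = open_slide(path, backend="array")
    truth = {"tissue_masks": masks, "blobs": blobs, "levels": levels}
    return handle, truth


def make_slide_tiff(spec: SlideSpec, path) -> dict:
    """Render a synthetic slide to a multi-page pyramidal TIFF on disk."""
    level0, tissue, blobs = _render_level0(spec)
    levels = _pyramid(level0, spec.n_levels)
    write_pyramid_tiff(levels, path)
    return {"tissue_masks": _mask_pyramid(tissue, spec.n_levels),
            "blobs": blobs, "levels": levels}


# ---------------------------------------------------------------------------
# two-cluster texture patches (self-supervision test bed)

def make_texture_patches(n: int = 500, size: int = 16, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Two patch clusters separable by texture frequency, not by any pixel
    direction.

    Each patch is a 2-D sinusoidal grating — low frequency for class 0, high
    for class 1 — with a *random phase* per patch, overlaid with a strong
    global brightness offset and per-channel gain nuisance plus pixel noise.
    The random phase makes class membership a power-spectrum (quadratic)
    feature invisible to linear probes on raw pixels or on random
    projections, while the brightness/gain nuisance is exactly the
    variation the color-jitter augmentation family removes: a contrastive
    encoder trained with those augmentations recovers the frequency
    clusters, a randomly initialized one drowns them in nuisance.

    Returns (patches uint8 (n, size, size, 3), labels (n,)).
    """
    rng = np.random.default_rng(seed)
    X = np.zeros((n, size, size, 3))
    y = np.zeros(n, dtype=int)
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n):
        lab = i % 2
        freq = 1.0 if lab == 0 else 4.0
        px, py = rng.uniform(0, 2 * np.pi, 2)
        tex = 60.0 * (np.sin(2 * np.pi * freq * xx / size + px)
                      * np.sin(2 * np.pi * freq * yy / size + py))
        base = 128.0 + rng.uniform(-80, 80)
        gains = 1.0 + rng.uniform(-0.3, 0.3, 3)
        img = (base + tex)[..., None] * gains + rng.normal(0, 5, (size, size, 3))
        X[i] = np.clip(img, 0, 255)
        y[i] = lab
    return X.astype(np.uint8), y


# ---------------------------------------------------------------------------
# witness bags

@dataclass(frozen=True)
class BagSpec:
    """Parameters of the witness-bag construction."""

    n_bags: int = 200
    instances_per_bag: int = 50
    d: int = 32
    witness_rate: float = 0.05
    shift: float = 1.5
    label_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.witness_rate <= 1.0):
            raise ParameterError("witness_rate must be in (0, 1]")
        if not (0.0 < self.label_balance < 1.0):
            raise ParameterError("label_balance must be in (0, 1)")


#: The frozen benchmark used throughout docs and the acceptance script:
#: 200 bags x 50 instances, d=32, 5% witnesses shifted 1.5 sigma, balanced.
STANDARD_BENCHMARK = BagSpec()


def make_bags(spec: BagSpec = BagSpec()) -> tuple[list[Bag], list[np.ndarray], np.ndarray]:
    """Generate witness bags.

    Returns (bags, witness_indices, direction): `witness_indices[i]` is the
    (possibly empty) sorted index array of witness instances in bag i, and
    `direction` is the planted unit vector along which witnesses are shifted.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.standard_normal(spec.d)
    u /= np.linalg.norm(u)

    n_pos = int(round(spec.n_bags * spec.label_balance))
    labels = np.array([1] * n_pos + [0] * (spec.n_bags - n_pos))
    rng.shuffle(labels)

    n_wit = int(np.rint(spec.witness_rate * spec.instances_per_bag))
    if n_wit < 1:
        warnings.warn("witness_rate x instances_per_bag < 1; clamped to 1 witness")
        n_wit = 1

    bags: list[Bag] = []
    witness_sets: list[np.ndarray] = []
    side = int(np.ceil(np.sqrt(spec.instances_per_bag)))
    base_coords = np.stack([(np.arange(spec.instances_per_bag) % side) * 224,
                            (np.arange(spec.instances_per_bag) // side) * 224],
                           axis=1).astype(np.int64)
    for i, y in enumerate(labels):
        H = rng.standard_normal((spec.instances_per_bag, spec.d))
        if y == 1:
            wit = np.sort(rng.choice(spec.instances_per_bag, size=n_wit,
                                     replace=False))
            H[wit] += spec.shift * u
        else:
            wit = np.empty(0, dtype=np.int64)
        bags.append(Bag(slide_id=f"bag{i:04d}", H=H, coords=base_coords.copy(),
                        label=int(y)))
        witness_sets.append(wit)
    return bags, witness_sets, u
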