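"""Tissue masking, patch-grid extraction and the per-slide collector.

H&E-stained tissue is dark (purple/pink) on a bright glass background, so
foreground/background separation reduces to a global grayscale threshold:
Otsu's criterion picks the cut maximizing between-class variance, and a little
binary morphology removes debris and fills small holes. The mask is computed
on a coarse pyramid level; patch candidates are then scanned on a regular
grid and kept when their tissue coverage (exact area-weighted overlap with
the mask) reaches a threshold.

The collector orchestrates mask -> grid (-> features) per slide over a worker
pool. Worker count never changes results; a failing slide is reported in the
summary instead of aborting the batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import DegenerateInputError, FormatError, ParameterError
from .slide_io import SlideHandle, level_for_max_dim, open_slide

__all__ = [
    "MaskParams",
    "TissueMask",
    "PatchGrid",
    "otsu_threshold",
    "compute_tissue_mask",
    "extract_patch_grid",
    "save_grid",
    "load_grid",
    "run_collector",
    "ColorStats",
    "normalize_color",
]

SCHEMA_VERSION = 1

# Rec. 601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class MaskParams:
    """Parameters of tissue-mask computation.

    mask_max_dim: the mask is computed on the coarsest stored pyramid level
    whose larger dimension does not exceed this budget (a virtual level is
    synthesized when no stored level fits). Areas are in pixels of that mask
    level.
    """

    mask_max_dim: int = 4096
    min_hole_area: int = 64
    min_object_area: int = 256
    morphology_radius: int = 2

    def __post_init__(self):
        if min(self.min_hole_area, self.min_object_area,
               self.morphology_radius) < 0:
            raise ParameterError("mask areas and radii must be non-negative")


@dataclass
class TissueMask:
    """Binary foreground mask at a stated pyramid level."""

    level: int                    # -1 when the level is virtual
    downsample: float             # level-0 pixels per mask pixel
    mask: np.ndarray              # 2-D bool
    otsu_threshold: int
    params: MaskParams
    virtual: bool = False

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class PatchGrid:
    """Retained patch positions for one slide.

    `coords` are top-left corners in the level-0 frame; `patch_size` and
    `step` are pixels at `patch_level`. `tissue_coverage[i]` is the exact
    area-weighted tissue fraction of patch i on the mask level.
    """

    slide_id: str
    patch_level: int
    patch_size: tuple[int, int]
    step: int
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    tissue_coverage: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    tissue_threshold: float = 0.5
    level_downsample: float = 1.0      # level-0 pixels per patch-level pixel

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.tissue_coverage = np.asarray(self.tissue_coverage,
                                          dtype=np.float32).reshape(-1)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def coords_at_patch_level(self) -> np.ndarray:
        """Top-left corners mapped from the level-0 frame to patch_level."""
        return np.rint(self.coords / self.level_downsample).astype(np.int64)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PatchGrid):
            return NotImplemented
        return (self.slide_id == other.slide_id
                and self.patch_level == other.patch_level
                and tuple(self.patch_size) == tuple(other.patch_size)
                and self.step == other.step
                and self.tissue_threshold == other.tissue_threshold
                and self.level_downsample == other.level_downsample
                and np.array_equal(self.coords, other.coords)
                and np.array_equal(self.tissue_coverage, other.tissue_coverage))


# ---------------------------------------------------------------------------
# Otsu thresholding

def otsu_threshold(gray: np.ndarray) -> int:
    """Between-class-variance-maximizing cut on the 256-bin histogram.

    The returned threshold t partitions pixels into {v < t} (dark, tissue)
    and {v >= t} (bright, glass). Among tied maximizers the smallest t is
    returned. Raises DegenerateInputError for a constant image, where no cut
    separates anything.
    """
    hist = np.bincount(np.asarray(gray, dtype=np.uint8).ravel(),
                       minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("no tissue separable: zero-variance histogram")
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    csum = np.cumsum(hist)            # pixels with value <= v
    cmoment = np.cumsum(hist * levels)
    # cut t in 1..255: class0 = {v < t} has csum[t-1] pixels
    n0 = csum[:-1]
    n1 = n - n0
    valid = (n0 > 0) & (n1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = cmoment[:-1] / n0
        m1 = (cmoment[-1] - cmoment[:-1]) / n1
        bcv = (n0 / n) * (n1 / n) * (m0 - m1) ** 2
    bcv[~valid] = -1.0
    return int(np.argmax(bcv)) + 1    # first (smallest) maximizer


def _to_gray(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img.astype(np.float64) @ _LUMA), 0, 255).astype(np.uint8)


def compute_tissue_mask(handle: SlideHandle, params: MaskParams = MaskParams()
                        ) -> TissueMask:
    """Segment tissue from glass on a coarse pyramid level.

    Steps: luma grayscale, Otsu cut, foreground = darker-than-threshold,
    remove objects < min_object_area, fill holes < min_hole_area, then
    morphological closing with a disk of morphology_radius.
    """
    from skimage.morphology import (closing, disk, remove_small_holes,
                                    remove_small_objects)

    img, level, downsample, virtual = level_for_max_dim(handle, params.mask_max_dim)
    gray = _to_gray(img)
    t = otsu_threshold(gray)
    fg = gray < t
    # max_size acts on areas <= its value; the contract here is strict
    # (remove objects < min_object_area, fill holes < min_hole_area)
    if params.min_object_area > 1:
        fg = remove_small_objects(fg, max_size=params.min_object_area - 1)
    if params.min_hole_area > 1:
        fg = remove_small_holes(fg, max_size=params.min_hole_area - 1)
    if params.morphology_radius > 0:
        fg = closing(fg, disk(params.morphology_radius))
    return TissueMask(level=level, downsample=float(downsample), mask=fg,
                      otsu_threshold=t, params=params, virtual=virtual)


# ---------------------------------------------------------------------------
# patch grid

def _rect_mask_mean(mask: np.ndarray, x0: float, x1: float,
                    y0: float, y1: float) -> float:
    """Exact area-weighted mean of a binary mask over a continuous rectangle."""
    h, w = mask.shape
    x0c, x1c = max(x0, 0.0), min(x1, float(w))
    y0c, y1c = max(y0, 0.0), min(y1, float(h))
    if x1c <= x0c or y1c <= y0c:
        return 0.0
    cx0, cx1 = int(math.floor(x0c)), int(math.ceil(x1c))
    cy0, cy1 = int(math.floor(y0c)), int(math.ceil(y1c))
    cols = np.arange(cx0, cx1, dtype=np.float64)
    rows = np.arange(cy0, cy1, dtype=np.float64)
    wx = np.minimum(cols + 1.0, x1c) - np.maximum(cols, x0c)
    wy = np.minimum(rows + 1.0, y1c) - np.maximum(rows, y0c)
    sub = mask[cy0:cy1, cx0:cx1].astype(np.float64)
    covered = float(wy @ sub @ wx)
    return covered / ((x1 - x0) * (y1 - y0))


def extract_patch_grid(handle: SlideHandle, mask: TissueMask,
                       patch_level: int = 0,
                       patch_size: int | tuple[int, int] = 224,
                       step: int | None = None,
                       tissue_threshold: float = 0.5) -> PatchGrid:
    """Raster-scan patch candidates and keep those covering enough tissue.

    Candidates start at (0, 0) of `patch_level` with stride `step` (default:
    non-overlapping, step = patch size). Coverage of each candidate is the
    exact fraction of its footprint, mapped onto the mask level, that is
    foreground. Retained iff coverage >= tissue_threshold. An empty grid is a
    valid result.
    """
    if not (0.0 <= tissue_threshold <= 1.0):
        raise ParameterError(
            f"tissue_threshold must be within [0, 1], got {tissue_threshold}")
    pw, ph = (patch_size, patch_size) if isinstance(patch_size, int) else patch_size
    if step is None:
        step = pw
    if step < 1:
        raise ParameterError("step must be >= 1")
    lw, lh = handle.level_dims[patch_level]
    if pw > lw or ph > lh:
        raise ParameterError(
            f"patch size {pw}x{ph} exceeds level {patch_level} dims {lw}x{lh}")
    ds_patch = handle.level_downsamples[patch_level]
    coords, coverage = [], []
    for y in range(0, lh - ph + 1, step):
        for x in range(0, lw - pw + 1, step):
            # candidate footprint in the level-0 frame, then on the mask level
            x0_l0, y0_l0 = x * ds_patch, y * ds_patch
            x1_l0, y1_l0 = (x + pw) * ds_patch, (y + ph) * ds_patch
            cov = _rect_mask_mean(mask.mask,
                                  x0_l0 / mask.downsample, x1_l0 / mask.downsample,
                                  y0_l0 / mask.downsample, y1_l0 / mask.downsample)
            if cov >= tissue_threshold:
                coords.append((int(round(x0_l0)), int(round(y0_l0))))
                coverage.append(cov)
    return PatchGrid(
        slide_id=handle.slide_id,
        patch_level=patch_level,
        patch_size=(pw, ph),
        step=step,
        coords=np.asarray(coords, dtype=np.int64).reshape(-1, 2),
        tissue_coverage=np.asarray(coverage, dtype=np.float32),
        tissue_threshold=float(tissue_threshold),
        level_downsample=float(ds_patch),
    )


# ---------------------------------------------------------------------------
# HDF5 per-slide store

def _write_grid_group(f: h5py.File, grid: PatchGrid) -> None:
    if "patches" in f:
        del f["patches"]
    g = f.create_group("patches")
    g.create_dataset("coords", data=grid.coords, dtype=np.int64)
    g.create_dataset("coverage", data=grid.tissue_coverage, dtype=np.float32)
    g.attrs["patch_level"] = grid.patch_level
    g.attrs["patch_size"] = list(grid.patch_size)
    g.attrs["step"] = grid.step
    g.attrs["tissue_threshold"] = grid.tissue_threshold
    g.attrs["level_downsample"] = grid.level_downsample
    g.attrs["slide_id"] = grid.slide_id


def _write_mask_group(f: h5py.File, mask: TissueMask) -> None:
    if "mask" in f:
        del f["mask"]
    g = f.create_group("mask")
    g.create_dataset("mask", data=mask.mask.astype(np.uint8))
    g.attrs["level"] = mask.level
    g.attrs["downsample"] = mask.downsample
    g.attrs["otsu_threshold"] = mask.otsu_threshold
    g.attrs["virtual"] = mask.virtual


def save_grid(grid: PatchGrid, path, mask: TissueMask | None = None) -> None:
    """Write a patch grid (and optionally the mask) to a per-slide HDF5 store."""
    with h5py.File(path, "a") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        _write_grid_group(f, grid)
        if mask is not None:
            _write_mask_group(f, mask)


def load_grid(path) -> PatchGrid:
    """Load a patch grid saved by :func:`save_grid`; round-trips exactly."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise FormatError(
                f"schema_version {version} unsupported (expected {SCHEMA_VERSION})")
        if "patches" not in f:
            raise FormatError("store is missing the 'patches' group")
        g = f["patches"]
        if "coords" not in g:
            raise FormatError("patch store is missing the 'coords' dataset")
        if "coverage" not in g:
            raise FormatError("patch store is missing the 'coverage' dataset")
        return PatchGrid(
            slide_id=str(g.attrs["slide_id"]),
            patch_level=int(g.attrs["patch_level"]),
            patch_size=tuple(int(v) for v in g.attrs["patch_size"]),
            step=int(g.attrs["step"]),
            coords=g["coords"][()],
            tissue_coverage=g["coverage"][()],
            tissue_threshold=float(g.attrs["tissue_threshold"]),
            level_downsample=float(g.attrs.get("level_downsample", 1.0)),
        )


# ---------------------------------------------------------------------------
# collector

def _collect_one(args) -> dict:
    (path, out_dir, mask_params, grid_kwargs, encoder_spec) = args
    from pathlib import Path
    try:
        handle = open_slide(path)
        mask = compute_tissue_mask(handle, mask_params)
        grid = extract_patch_grid(handle, mask, **grid_kwargs)
        store = Path(out_dir) / f"{handle.slide_id}.h5"
        save_grid(grid, store, mask=mask)
        if encoder_spec is not None and len(grid):
            from .encode import encode_bag
            encode_bag(handle, grid, encoder_spec, store=store)
        return {"slide_id": handle.slide_id, "n_patches": len(grid),
                "status": "ok", "error": ""}
    except Exception as exc:  # a failing slide must not sink the batch
        from pathlib import Path as _P
        return {"slide_id": _P(str(path)).stem, "n_patches": 0,
                "status": "failed", "error": f"{type(exc).__name__}: {exc}"}


def run_collector(slide_paths, out_dir, mask_params: MaskParams = MaskParams(),
                  workers: int = 1, encoder_spec=None, **grid_kwargs):
    """Process a batch of slides (mask -> grid [-> features]) into HDF5 stores.

    Returns a summary DataFrame with one row per slide (slide_id, n_patches,
    status, error), in input order. Results are identical for any worker
    count; parallelism only affects wall time.
    """
    import pandas as pd

    if workers < 1:
        raise ParameterError("workers must be >= 1")
    jobs = [(str(p), str(out_dir), mask_params, grid_kwargs, encoder_spec)
            for p in slide_paths]
    if workers == 1 or len(jobs) <= 1:
        rows = [_collect_one(j) for j in jobs]
    else:
        import multiprocessing as mp
        with mp.get_context("fork").Pool(processes=workers) as pool:
            rows = pool.map(_collect_one, jobs)
    return pd.DataFrame(rows, columns=["slide_id", "n_patches", "status", "error"])


# ---------------------------------------------------------------------------
# Reinhard-style color normalization

@dataclass(frozen=True)
class ColorStats:
    """Per-channel mean/std in the CIELAB space (decorrelated for H&E)."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    @classmethod
    def from_image(cls, img: np.ndarray) -> "ColorStats":
        from skimage.color import rgb2lab

        lab = rgb2lab(np.asarray(img, dtype=np.float64) / 255.0)
        flat = lab.reshape(-1, 3)
        return cls(mean=tuple(flat.mean(axis=0)), std=tuple(flat.std(axis=0)))


def normalize_color(patch: np.ndarray, reference: ColorStats) -> np.ndarray:
    """Shift/scale each LAB channel of `patch` to the reference statistics.

    A zero-variance source channel is passed through unchanged (with a
    warning); a fully constant patch is returned as-is.
    """
    from skimage.color import lab2rgb, rgb2lab

    src = ColorStats.from_image(patch)
    if all(s < 1e-8 for s in src.std):
        warnings.warn("constant-color patch: color normalization skipped")
        return patch.copy()
    lab = rgb2lab(np.asarray(patch, dtype=np.float64) / 255.0)
    out = lab.copy()
    for c in range(3):
        if src.std[c] < 1e-8:
            warnings.warn(f"zero-variance channel {c}: scaling skipped")
            continue
        out[..., c] = ((lab[..., c] - src.mean[c]) / src.std[c]
                       * reference.std[c] + reference.mean[c])
    rgb = np.clip(lab2rgb(out), 0.0, 1.0)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
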