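"""Backend-agnostic whole-slide reading.

Whole-slide images (WSIs) are gigapixel scans stored as a multi-resolution
pyramid: level 0 is the full-resolution scan and each coarser level is a
downsampled rendering. Vendors ship many on-disk formats, so this module keeps
the rest of the pipeline independent of any one reader: a backend adapter
turns a file into pyramid arrays plus metadata, and every downstream step
talks only to :class:`SlideHandle` / :func:`read_region`.

Coordinate convention (used across the whole package): region origins are
(x, y) pixel coordinates in the level-0 frame, region sizes are pixels in the
target-level frame, and all pixel intervals are 0-based and half-open.

Three adapters are bundled:

``tiff``
    Pyramidal or single-level TIFF via :mod:`tifffile`. Multi-page files are
    interpreted as one pyramid level per page (largest first).
``pil``
    Single-level PNG/JPEG via Pillow.
``array``
    In-memory pyramids registered under ``mem://<key>`` — used by the
    synthetic fixtures and handy for tests of custom pipelines.

Additional readers (e.g. an OpenSlide wrapper) plug in through
:func:`register_backend`; they only need the four-member adapter contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BoundsError, ConfigurationError, ContractError, FormatError

__all__ = [
    "SlideHandle",
    "RegionRequest",
    "SlideBackend",
    "register_backend",
    "registered_backends",
    "open_slide",
    "read_region",
    "read_level",
    "block_mean_downsample",
    "write_pyramid_tiff",
    "register_memory_slide",
]


# ---------------------------------------------------------------------------
# utilities

def to_rgb8(arr: np.ndarray) -> np.ndarray:
    """Coerce an image array to H x W x 3 uint8; alpha composited over white."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.shape[-1] == 4:
        rgb = a[..., :3].astype(np.float64)
        alpha = a[..., 3:4].astype(np.float64) / 255.0
        a = rgb * alpha + 255.0 * (1.0 - alpha)
    if a.dtype != np.uint8:
        a = np.clip(np.rint(a), 0, 255).astype(np.uint8)
    return np.ascontiguousarray(a[..., :3])


def block_mean_downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by an integer factor with block averaging (uint8 in/out).

    Trailing rows/columns that do not fill a complete block are dropped, so
    the output has shape (H // factor, W // factor, ...).
    """
    if factor == 1:
        return arr.copy()
    h, w = arr.shape[:2]
    hb, wb = h // factor, w // factor
    a = arr[: hb * factor, : wb * factor].astype(np.float64)
    if a.ndim == 2:
        blocks = a.reshape(hb, factor, wb, factor).mean(axis=(1, 3))
    else:
        blocks = a.reshape(hb, factor, wb, factor, -1).mean(axis=(1, 3))
    return np.clip(np.rint(blocks), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# backend contract

class SlideBackend:
    """Abstract adapter contract for slide readers.

    A conforming adapter provides::

        open(path)          classmethod/constructor -> adapter instance
        level_dims          list of (width, height), level 0 largest
        level_downsamples   list of floats, element 0 == 1.0
        read_region(level, origin_l0, size) -> H x W x 3 uint8

    ``mpp`` (microns per pixel at level 0) is optional and may be None.
    """

    level_dims: list[tuple[int, int]] = None  # type: ignore[assignment]
    level_downsamples: list[float] = None     # type: ignore[assignment]
    mpp: float | None = None

    @classmethod
    def open(cls, path):  # pragma: no cover - abstract
        raise NotImplementedError

    def read_region(self, level: int, origin, size) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _ArrayPyramidBackend(SlideBackend):
    """Serve regions from a list of in-memory level arrays (finest first)."""

    def __init__(self, levels: list[np.ndarray], mpp: float | None = None):
        self._levels = [to_rgb8(a) for a in levels]
        self.level_dims = [(a.shape[1], a.shape[0]) for a in self._levels]
        w0 = self.level_dims[0][0]
        self.level_downsamples = [w0 / w for (w, _h) in self.level_dims]
        self.mpp = mpp

    @classmethod
    def open(cls, path):
        raise NotImplementedError

    def level_array(self, level: int) -> np.ndarray:
        return self._levels[level]

    def read_region(self, level: int, origin, size) -> np.ndarray:
        ds = self.level_downsamples[level]
        x = int(origin[0] / ds)
        y = int(origin[1] / ds)
        w, h = size
        return self._levels[level][y:y + h, x:x + w].copy()


class TiffBackend(_ArrayPyramidBackend):
    """TIFF reader; pyramidal series or one level per page, largest first."""

    @classmethod
    def open(cls, path):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            if series.levels and len(series.levels) > 1:
                arrays = [lvl.asarray() for lvl in series.levels]
            elif len(tf.pages) > 1:
                arrays = [p.asarray() for p in tf.pages]
            else:
                arrays = [series.asarray()]
        arrays.sort(key=lambda a: -(a.shape[0] * a.shape[1]))
        return cls(arrays)


class PilBackend(_ArrayPyramidBackend):
    """Single-level PNG/JPEG reader via Pillow."""

    @classmethod
    def open(cls, path):
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGBA") if im.mode == "RGBA" else im)
        return cls([arr])


_MEMORY_SLIDES: dict[str, list[np.ndarray]] = {}


def register_memory_slide(key: str, levels: list[np.ndarray]) -> str:
    """Store an in-memory pyramid; returns the ``mem://`` path that opens it."""
    _MEMORY_SLIDES[key] = [to_rgb8(a) for a in levels]
    return f"mem://{key}"


class ArrayBackend(_ArrayPyramidBackend):
    """Backend for pyramids registered with :func:`register_memory_slide`."""

    @classmethod
    def open(cls, path):
        key = str(path)
        key = key[len("mem://"):] if key.startswith("mem://") else key
        if key not in _MEMORY_SLIDES:
            raise FileNotFoundError(f"no in-memory slide registered as {key!r}")
        return cls(_MEMORY_SLIDES[key])


_REQUIRED_MEMBERS = ("open", "read_region", "level_dims", "level_downsamples")
_BACKENDS: dict[str, type] = {}


def register_backend(name: str, adapter: type) -> None:
    """Register a reader adapter under `name`; replaces an existing entry."""
    missing = [m for m in _REQUIRED_MEMBERS if not hasattr(adapter, m)]
    if missing:
        raise ContractError(
            f"backend adapter {adapter!r} is missing required member(s): "
            + ", ".join(missing)
        )
    _BACKENDS[name] = adapter


def registered_backends() -> list[str]:
    return sorted(_BACKENDS)


register_backend("tiff", TiffBackend)
register_backend("pil", PilBackend)
register_backend("array", ArrayBackend)


# ---------------------------------------------------------------------------
# handle and region access

@dataclass(frozen=True)
class RegionRequest:
    """A rectangular read: `origin` in the level-0 frame, `size` at `level`."""

    level: int
    origin: tuple[int, int]
    size: tuple[int, int]


@dataclass
class SlideHandle:
    """An open slide: pyramid metadata plus a region-read capability."""

    slide_id: str
    level_count: int
    level_dims: list[tuple[int, int]]
    level_downsamples: list[float]
    backend_name: str
    mpp: float | None = None
    virtual_levels: frozenset[int] = frozenset()
    _adapter: SlideBackend = field(default=None, repr=False)

    def __post_init__(self):
        if self.level_count < 1 or len(self.level_dims) != self.level_count:
            raise FormatError("pyramid metadata inconsistent: bad level count")
        w0, h0 = self.level_dims[0]
        for k in range(1, self.level_count):
            wk, hk = self.level_dims[k]
            wp, hp = self.level_dims[k - 1]
            if wk > wp or hk > hp:
                raise FormatError("level dims must be non-increasing")
            if self.level_downsamples[k] <= self.level_downsamples[k - 1]:
                raise FormatError("level downsamples must be strictly increasing")
        for k, ((wk, _hk), ds) in enumerate(zip(self.level_dims,
                                                self.level_downsamples)):
            if abs(ds - w0 / wk) > 0.01 * ds:
                raise FormatError(
                    f"level {k}: stored downsample {ds} disagrees with "
                    f"dimensions {w0}/{wk} by more than 1%"
                )

    @property
    def dimensions(self) -> tuple[int, int]:
        return self.level_dims[0]

    def read_region(self, req: RegionRequest) -> np.ndarray:
        return read_region(self, req)


def open_slide(path, backend: str | None = None) -> SlideHandle:
    """Open a slide file through a registered backend.

    With ``backend=None`` the backend is inferred from the path: ``mem://``
    keys use the in-memory backend, ``.tif/.tiff`` the TIFF backend, other
    raster suffixes the Pillow backend.
    """
    spath = str(path)
    if backend is None:
        if spath.startswith("mem://"):
            backend = "array"
        elif spath.lower().endswith((".tif", ".tiff")):
            backend = "tiff"
        else:
            backend = "pil"
    if backend not in _BACKENDS:
        raise ConfigurationError(
            f"unknown slide backend {backend!r}; registered: {registered_backends()}"
        )
    try:
        adapter = _BACKENDS[backend].open(spath)
    except (ConfigurationError, ContractError):
        raise
    except Exception as exc:
        raise FormatError(
            f"backend {backend!r} could not read {spath!r}: {exc}"
        ) from exc

    slide_id = Path(spath.replace("mem://", "")).stem
    return SlideHandle(
        slide_id=slide_id,
        level_count=len(adapter.level_dims),
        level_dims=[tuple(d) for d in adapter.level_dims],
        level_downsamples=[float(d) for d in adapter.level_downsamples],
        backend_name=backend,
        mpp=adapter.mpp,
        _adapter=adapter,
    )


def read_region(handle: SlideHandle, req: RegionRequest) -> np.ndarray:
    """Read a region; output is exactly ``req.size`` as (h, w, 3) uint8."""
    if not (0 <= req.level < handle.level_count):
        raise BoundsError(
            f"level {req.level} outside [0, {handle.level_count})"
        )
    ds = handle.level_downsamples[req.level]
    lw, lh = handle.level_dims[req.level]
    x = int(req.origin[0] / ds)
    y = int(req.origin[1] / ds)
    w, h = req.size
    if x < 0 or y < 0 or x + w > lw or y + h > lh:
        raise BoundsError(
            f"region origin={req.origin} size={req.size} at level {req.level} "
            f"maps to [{x}, {x + w}) x [{y}, {y + h}) outside {lw} x {lh}"
        )
    out = handle._adapter.read_region(req.level, req.origin, req.size)
    out = to_rgb8(out)
    if out.shape[:2] != (h, w):
        raise BoundsError(f"backend returned {out.shape[:2]}, expected {(h, w)}")
    return out


def read_level(handle: SlideHandle, level: int) -> np.ndarray:
    """Read an entire pyramid level."""
    w, h = handle.level_dims[level]
    return read_region(handle, RegionRequest(level=level, origin=(0, 0),
                                             size=(w, h)))


def level_for_max_dim(handle: SlideHandle, max_dim: int) -> tuple[np.ndarray, int, float, bool]:
    """Pick the coarsest stored level with max dimension <= `max_dim`.

    If even the coarsest stored level exceeds the budget, a virtual level is
    synthesized by block-mean downsampling it (factor doubled until it fits).
    Returns (image, level_index_or_-1, downsample, is_virtual).
    """
    for k in range(handle.level_count - 1, -1, -1):
        w, h = handle.level_dims[k]
        if max(w, h) <= max_dim:
            return read_level(handle, k), k, handle.level_downsamples[k], False
    coarsest = handle.level_count - 1
    img = read_level(handle, coarsest)
    ds = handle.level_downsamples[coarsest]
    factor = 1
    while max(img.shape[:2]) // factor > max_dim:
        factor *= 2
    img = block_mean_downsample(img, factor)
    return img, -1, ds * factor, True


def write_pyramid_tiff(levels: list[np.ndarray], path) -> None:
    """Write level arrays (finest first) as a multi-page TIFF."""
    import tifffile

    with tifffile.TiffWriter(str(path)) as tw:
        for arr in levels:
            tw.write(to_rgb8(arr), photometric="rgb")
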