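"""Slide-space heatmaps of per-patch scores.

A trained MIL head assigns each patch an attention weight or probability;
projecting those back onto the slide shows where in the tissue the model
found its evidence (or where a marker is predicted active). Scores are laid
out on the patch grid, min-max normalized per slide, mapped through the
perceptually uniform purple-to-yellow ramp (viridis) and alpha-blended over
the slide rendering; cells outside tissue stay untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ShapeError
from .preprocess import PatchGrid
from .slide_io import SlideHandle, read_level

__all__ = ["Heatmap", "build_score_map", "render_heatmap", "scores_to_csv"]


@dataclass
class Heatmap:
    level: int
    image: np.ndarray                  # H x W x 3 uint8 overlay
    score_map: np.ndarray              # cells; NaN where no patch
    normalization: str


def build_score_map(grid: PatchGrid, instance_scores) -> np.ndarray:
    """Place per-patch scores on the patch grid.

    One cell per stride position; a patch larger than the stride covers
    several cells and overlapping patches are averaged per cell. Cells with
    no patch are NaN.
    """
    scores = np.asarray(instance_scores, dtype=np.float64).reshape(-1)
    if scores.shape[0] != len(grid):
        raise ShapeError(
            f"{scores.shape[0]} scores for {len(grid)} patches")
    pw, ph = grid.patch_size
    step = grid.step
    acc = {}
    cnt = {}
    max_cx = max_cy = 0
    for (x0, y0), s in zip(grid.coords_at_patch_level(), scores):
        cx0, cy0 = x0 // step, y0 // step
        cx1 = int(np.ceil((x0 + pw) / step))
        cy1 = int(np.ceil((y0 + ph) / step))
        for cy in range(cy0, cy1):
            for cx in range(cx0, cx1):
                acc[(cy, cx)] = acc.get((cy, cx), 0.0) + s
                cnt[(cy, cx)] = cnt.get((cy, cx), 0) + 1
                max_cx, max_cy = max(max_cx, cx), max(max_cy, cy)
    out = np.full((max_cy + 1, max_cx + 1) if acc else (0, 0), np.nan)
    for key, total in acc.items():
        out[key] = total / cnt[key]
    return out


def render_heatmap(handle: SlideHandle, score_map: np.ndarray, grid: PatchGrid,
                   level: int | None = None, alpha: float = 0.6,
                   normalization: str = "minmax", out_path=None) -> Heatmap:
    """Blend a score map over the slide rendering at a pyramid level.

    Present scores are min-max normalized to [0, 1] (a constant map renders
    at 0.5); `normalization='none'` clips raw scores to [0, 1] instead.
    Absent cells keep the original slide pixels.
    """
    from matplotlib import colormaps

    if score_map.size == 0 or not np.isfinite(score_map).any():
        raise ParameterError("empty score map: nothing to render")
    if level is None:
        level = handle.level_count - 1
    base = read_level(handle, level).astype(np.float64)
    ds_level = handle.level_downsamples[level]
    ds_patch = handle.level_downsamples[grid.patch_level]
    cell_px = grid.step * ds_patch / ds_level   # cell size at render level

    present = np.isfinite(score_map)
    vals = score_map[present]
    if normalization == "minmax":
        vmin, vmax = vals.min(), vals.max()
        norm = np.full_like(score_map, np.nan)
        if vmax > vmin:
            norm[present] = (score_map[present] - vmin) / (vmax - vmin)
        else:
            norm[present] = 0.5
    elif normalization == "none":
        norm = np.clip(score_map, 0.0, 1.0)
        norm[~present] = np.nan
    else:
        raise ParameterError(f"unknown normalization {normalization!r}")

    cmap = colormaps["viridis"]
    out = base.copy()
    ny, nx = score_map.shape
    for cy in range(ny):
        for cx in range(nx):
            if not np.isfinite(norm[cy, cx]):
                continue
            color = np.array(cmap(float(norm[cy, cx]))[:3]) * 255.0
            y0 = int(round(cy * cell_px))
            y1 = int(round((cy + 1) * cell_px))
            x0 = int(round(cx * cell_px))
            x1 = int(round((cx + 1) * cell_px))
            region = out[y0:y1, x0:x1]
            out[y0:y1, x0:x1] = (1.0 - alpha) * region + alpha * color
    image = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if out_path is not None:
        from PIL import Image

        Image.fromarray(image).save(str(out_path), format="PNG")
    return Heatmap(level=level, image=image, score_map=score_map,
                   normalization=normalization)


def scores_to_csv(grid: PatchGrid, instance_scores, path) -> None:
    """Write (x, y, score) rows in the level-0 frame."""
    import pandas as pd

    scores = np.asarray(instance_scores).reshape(-1)
    if scores.shape[0] != len(grid):
        raise ShapeError("score/patch count mismatch")
    pd.DataFrame({"x": grid.coords[:, 0], "y": grid.coords[:, 1],
                  "score": scores}).to_csv(path, index=False)
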