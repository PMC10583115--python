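"""Tissue masking, patch grids, HDF5 round trips, the collector, color."""

import numpy as np
import pytest

from milslide.errors import DegenerateInputError, FormatError, ParameterError
from milslide.fixtures import SlideSpec, make_slide, make_slide_tiff
from milslide.preprocess import (ColorStats, MaskParams, PatchGrid, TissueMask,
                                 compute_tissue_mask, extract_patch_grid,
                                 load_grid, normalize_color, otsu_threshold,
                                 run_collector, save_grid)
from milslide.slide_io import register_memory_slide, open_slide


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive search over all 255 cuts, ties -> smallest threshold."""
    g = gray.ravel().astype(float)
    n = g.size
    best_t, best_v = None, -1.0
    for t in range(1, 256):
        lo, hi = g[g < t], g[g >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_matches_exhaustive_search_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_modes = rng.integers(1, 4)
            vals = np.concatenate([
                rng.normal(rng.integers(30, 220), rng.integers(5, 40),
                           rng.integers(50, 300))
                for _ in range(n_modes)])
            gray = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
            if gray.min() == gray.max():
                continue
            assert otsu_threshold(gray) == brute_force_otsu(gray)

    def test_two_valued_image(self):
        gray = np.array([10] * 50 + [200] * 50, dtype=np.uint8)
        t = otsu_threshold(gray)
        assert 10 < t <= 200
        assert t == brute_force_otsu(gray)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="no tissue separable"):
            otsu_threshold(np.full((10, 10), 77, dtype=np.uint8))


class TestTissueMask:
    def test_blob_foreground_area_within_5_percent(self, blob_slide):
        handle, truth = blob_slide
        mask = compute_tissue_mask(handle, MaskParams())
        gt = truth["tissue_masks"][-1]          # mask computed at coarsest level
        assert mask.mask.shape == gt.shape
        assert abs(mask.mask.mean() - gt.mean()) <= 0.05 * gt.mean()

    def test_threshold_maximizes_between_class_variance(self, blob_slide):
        handle, _ = blob_slide
        from milslide.preprocess import _to_gray
        from milslide.slide_io import read_level

        mask = compute_tissue_mask(handle, MaskParams())
        gray = _to_gray(read_level(handle, handle.level_count - 1))
        assert mask.otsu_threshold == brute_force_otsu(gray)

    def test_hole_fill_respects_min_hole_area(self):
        img = np.full((128, 128), 230, np.uint8)
        img[20:80, 20:80] = 60                   # dark tissue square
        img[40:42, 40:42] = 230                  # 4-pixel bright hole
        path = register_memory_slide("hole-slide", [np.stack([img] * 3, -1)])
        h = open_slide(path, backend="array")
        params = dict(mask_max_dim=4096, min_object_area=16,
                      morphology_radius=0)
        filled = compute_tissue_mask(h, MaskParams(min_hole_area=64, **params))
        kept = compute_tissue_mask(h, MaskParams(min_hole_area=1, **params))
        assert filled.mask[40, 40]
        assert not kept.mask[40, 40]


class TestPatchGrid:
    def test_all_tissue_448_gives_exactly_four_patches(self, all_tissue_mask_448):
        img = np.full((448, 448, 3), 120, np.uint8)
        h = open_slide(register_memory_slide("t448", [img]), backend="array")
        grid = extract_patch_grid(h, all_tissue_mask_448, patch_size=224,
                                  step=224, tissue_threshold=0.5)
        assert sorted(map(tuple, grid.coords.tolist())) == \
            [(0, 0), (0, 224), (224, 0), (224, 224)]
        assert np.allclose(grid.tissue_coverage, 1.0)

    def test_all_glass_gives_zero_patches(self, all_tissue_mask_448):
        img = np.full((448, 448, 3), 240, np.uint8)
        h = open_slide(register_memory_slide("g448", [img]), backend="array")
        mask = TissueMask(level=0, downsample=1.0,
                          mask=np.zeros((448, 448), bool),
                          otsu_threshold=128, params=MaskParams())
        grid = extract_patch_grid(h, mask, patch_size=224, step=224)
        assert len(grid) == 0

    def test_half_tissue_slide_keeps_left_half_patches(self):
        # tissue occupies exactly the left half of an 896 x 448 slide
        img = np.full((448, 896, 3), 240, np.uint8)
        img[:, :448] = 90
        h = open_slide(register_memory_slide("half896", [img]), backend="array")
        gt = np.zeros((448, 896), bool)
        gt[:, :448] = True
        mask = TissueMask(level=0, downsample=1.0, mask=gt,
                          otsu_threshold=128, params=MaskParams())
        grid = extract_patch_grid(h, mask, patch_size=224, step=224,
                                  tissue_threshold=0.5)
        # oracle: coverage from the ground-truth mask, center-in-left-half
        expected = []
        for y in range(0, 448 - 223, 224):
            for x in range(0, 896 - 223, 224):
                cov = gt[y:y + 224, x:x + 224].mean()
                if cov >= 0.5:
                    expected.append((x, y))
        assert sorted(map(tuple, grid.coords.tolist())) == sorted(expected)
        assert all(x + 112 <= 448 for x, _ in grid.coords)

    def test_candidate_count_formula(self):
        img = np.full((300, 500, 3), 100, np.uint8)
        h = open_slide(register_memory_slide("c500", [img]), backend="array")
        mask = TissueMask(level=0, downsample=1.0, mask=np.ones((300, 500), bool),
                          otsu_threshold=128, params=MaskParams())
        w, s = 64, 48
        grid = extract_patch_grid(h, mask, patch_size=w, step=s,
                                  tissue_threshold=0.0)
        nx = (500 - w) // s + 1
        ny = (300 - w) // s + 1
        assert len(grid) == nx * ny

    def test_raising_threshold_never_adds_patches(self, multi_blob_slide):
        handle, _ = multi_blob_slide
        mask = compute_tissue_mask(handle, MaskParams())
        counts = [len(extract_patch_grid(handle, mask, patch_size=64, step=64,
                                         tissue_threshold=t))
                  for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_outside_unit_interval_rejected(self, blob_slide):
        handle, _ = blob_slide
        mask = compute_tissue_mask(handle)
        with pytest.raises(ParameterError):
            extract_patch_grid(handle, mask, tissue_threshold=1.5)


class TestGridStore:
    def test_round_trip_identity(self, tmp_path, grid_2x2):
        p = tmp_path / "g.h5"
        save_grid(grid_2x2, p)
        assert load_grid(p) == grid_2x2

    def test_empty_grid_round_trip(self, tmp_path):
        empty = PatchGrid(slide_id="e", patch_level=0, patch_size=(224, 224),
                          step=224)
        p = tmp_path / "e.h5"
        save_grid(empty, p)
        loaded = load_grid(p)
        assert loaded == empty
        assert len(loaded) == 0

    def test_missing_coords_dataset_named_in_error(self, tmp_path, grid_2x2):
        import h5py

        p = tmp_path / "broken.h5"
        save_grid(grid_2x2, p)
        with h5py.File(p, "a") as f:
            del f["patches/coords"]
        with pytest.raises(FormatError, match="coords"):
            load_grid(p)

    def test_schema_version_mismatch(self, tmp_path, grid_2x2):
        import h5py

        p = tmp_path / "old.h5"
        save_grid(grid_2x2, p)
        with h5py.File(p, "a") as f:
            f.attrs["schema_version"] = 99
        with pytest.raises(FormatError, match="schema_version"):
            load_grid(p)


@pytest.fixture(scope="module")
def slide_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("slides")
    for i in range(3):
        make_slide_tiff(SlideSpec(width=512, height=512, n_blobs=2,
                                  seed=20 + i), d / f"s{i}.tiff")
    return d


class TestCollector:
    def test_worker_count_does_not_change_results(self, slide_dir, tmp_path):
        out1, out2 = tmp_path / "w1", tmp_path / "w3"
        out1.mkdir(), out2.mkdir()
        paths = sorted(slide_dir.glob("*.tiff"))
        s1 = run_collector(paths, out1, workers=1, patch_size=64, step=64)
        s3 = run_collector(paths, out2, workers=3, patch_size=64, step=64)
        assert s1.equals(s3)
        for p in paths:
            assert load_grid(out1 / f"{p.stem}.h5") == \
                load_grid(out2 / f"{p.stem}.h5")

    def test_corrupt_slide_fails_alone(self, slide_dir, tmp_path):
        bad = tmp_path / "bad.tiff"
        bad.write_bytes(b"this is not a tiff")
        out = tmp_path / "out"
        out.mkdir()
        paths = sorted(slide_dir.glob("*.tiff")) + [bad]
        summary = run_collector(paths, out, workers=1, patch_size=64, step=64)
        assert (summary.status == "ok").sum() == 3
        failed = summary[summary.status == "failed"]
        assert list(failed.slide_id) == ["bad"]
        assert failed.error.iloc[0] != ""

    def test_summary_patch_count_matches_direct_extraction(self, tmp_path):
        d = tmp_path / "one"
        d.mkdir()
        make_slide_tiff(SlideSpec(width=448, height=448,
                                  blobs=((224, 224, 220, 220),),
                                  n_levels=1, seed=9), d / "one.tiff")
        out = tmp_path / "o"
        out.mkdir()
        summary = run_collector([d / "one.tiff"], out, patch_size=224, step=224)
        h = open_slide(d / "one.tiff")
        mask = compute_tissue_mask(h)
        grid = extract_patch_grid(h, mask, patch_size=224, step=224)
        assert summary.n_patches.iloc[0] == len(grid)


class TestColorNormalization:
    def test_self_normalization_is_identity(self):
        rng = np.random.default_rng(1)
        patch = rng.integers(40, 220, (64, 64, 3)).astype(np.uint8)
        out = normalize_color(patch, ColorStats.from_image(patch))
        assert np.abs(out.astype(int) - patch.astype(int)).max() <= 1

    def test_brightness_shift_collapses_to_same_output(self):
        rng = np.random.default_rng(2)
        a = rng.integers(60, 180, (64, 64, 3)).astype(np.uint8)
        b = np.clip(a.astype(int) + 8, 0, 255).astype(np.uint8)
        ref = ColorStats(mean=(60.0, 5.0, -5.0), std=(12.0, 6.0, 6.0))
        out_a = normalize_color(a, ref).astype(int)
        out_b = normalize_color(b, ref).astype(int)
        assert np.abs(out_a - out_b).max() <= 2

    def test_constant_patch_returned_unchanged_with_warning(self):
        patch = np.full((32, 32, 3), 128, np.uint8)
        ref = ColorStats(mean=(50.0, 0.0, 0.0), std=(10.0, 5.0, 5.0))
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_color(patch, ref)
        assert np.array_equal(out, patch)
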