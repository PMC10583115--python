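import numpy as np
import pytest

from milslide.fixtures import SlideSpec, make_slide
from milslide.preprocess import MaskParams, PatchGrid, TissueMask


@pytest.fixture(scope="session")
def blob_slide():
    """1024 px pyramidal slide with one centered 400 x 300 elliptical blob."""
    handle, truth = make_slide(SlideSpec(width=1024, height=1024,
                                         blobs=((512, 512, 200, 150),), seed=3))
    return handle, truth


@pytest.fixture(scope="session")
def multi_blob_slide():
    handle, truth = make_slide(SlideSpec(width=512, height=512, n_blobs=2, seed=7))
    return handle, truth


@pytest.fixture()
def all_tissue_mask_448():
    """Full-coverage mask for a 448 x 448 single-level slide."""
    return TissueMask(level=0, downsample=1.0, mask=np.ones((448, 448), bool),
                      otsu_threshold=128, params=MaskParams())


@pytest.fixture()
def grid_2x2():
    """Four non-overlapping 224 px patches tiling a 448 px slide."""
    return PatchGrid(slide_id="s", patch_level=0, patch_size=(224, 224),
                     step=224,
                     coords=np.array([[0, 0], [224, 0], [0, 224], [224, 224]]),
                     tissue_coverage=np.ones(4, np.float32),
                     tissue_threshold=0.5, level_downsample=1.0)
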