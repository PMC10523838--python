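"""Shared fixtures: the smoke training set and a model trained on it.

The smoke set is 16 synthetic 64x64 images with disjoint bright somas
(NMDA/washout intensity regimes) over textured neuropil; training it to
convergence takes a couple of minutes on one CPU, so the fitted estimator
is session-scoped and reused by the detector and acceptance tests.
"""

import numpy as np
import pytest

from somaswin.detector import SomaSwinSegmenter
from somaswin.simulate import (
    GeneratorConfig,
    build_cell_bank,
    build_tile_bank,
    synthesize_image,
)

SMOKE_SEED = 11
SMOKE_N_IMAGES = 16

TINY_PARAMS = dict(embed_dim=32, depths=(1, 1, 1, 1), num_heads=(2, 4, 8, 16),
                   window_size=4, fuse_dim=32, seed=0)


def make_smoke_dataset(n_images: int = SMOKE_N_IMAGES, seed: int = SMOKE_SEED):
    """Bright disjoint somas on neuropil texture, with ground-truth masks."""
    cfg = GeneratorConfig(n_images=n_images, image_size=(64, 64),
                          cells_per_image=(2, 4), max_pairwise_overlap_iou=0.0,
                          min_separation_px=3, condition_mix=(0.0, 0.6, 0.4),
                          seed=seed)
    rng = np.random.default_rng(1)
    cells = build_cell_bank(24, rng, condition_mix=(0.0, 0.6, 0.4),
                            radius_range=(4.0, 7.0))
    tiles = build_tile_bank(12, (32, 32), rng)
    images, gt_masks = [], []
    for i in range(n_images):
        syn = synthesize_image(cfg, cells, tiles, 1000 + i)
        images.append(syn.pixels)
        gt_masks.append(syn.instances)
    return images, gt_masks


@pytest.fixture(scope="session")
def smoke_dataset():
    return make_smoke_dataset()


@pytest.fixture(scope="session")
def trained_segmenter(smoke_dataset):
    images, gt_masks = smoke_dataset
    est = SomaSwinSegmenter(epochs=300, batch_size=4, lr=3e-3, **TINY_PARAMS)
    est.fit(images, gt_masks)
    return est


@pytest.fixture
def rng():
    return np.random.default_rng(0)
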