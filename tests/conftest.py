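"""Shared fixtures: geometric masks and a small simulated clustered dataset.

All fixtures are generated programmatically; the simulated dataset is
session-scoped because segmenting it at several revised-factor settings is
the slow part of the suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from skimage.draw import disk

from cellcut.preprocess import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_disk_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


@pytest.fixture
def disk_mask():
    """Single convex disk, radius 10."""
    return BinaryMask(make_disk_mask((40, 40), (20, 20), 10))


@pytest.fixture
def touching_pair():
    """Two disks overlapping by ~2 px: one component, two cells."""
    m = make_disk_mask((60, 90), (30, 25), 13)
    m |= make_disk_mask((60, 90), (30, 49), 13)
    return BinaryMask(m)


@pytest.fixture(scope="session")
def three_touching_disks():
    """Three mutually touching disks (the canonical worked example)."""
    m = np.zeros((100, 100), dtype=bool)
    for center in [(35, 35), (35, 66), (62, 50)]:
        m |= make_disk_mask((100, 100), center, 16)
    return BinaryMask(m)


@pytest.fixture(scope="session")
def sim_dataset():
    """Three clustered synthetic images (600x600, 120 cells) with truth."""
    from cellcut.simulate import generate, preset

    out = []
    for seed in (11, 12, 13):
        params = preset(
            "simcep_set1", seed=seed, image_size=(600, 600), n_cells=120
        )
        img, truth = generate(params)
        out.append((img, truth, params))
    return out


@pytest.fixture(scope="session")
def sim_sweep_scores(sim_dataset):
    """Detection scores of the segmenter on ``sim_dataset`` across the
    revised-factor grid used by the parameter-behavior checks."""
    from cellcut.evaluate import evaluate_detection
    from cellcut.ncut import CutConfig
    from cellcut.pipeline import SegmentationConfig, segment_image

    grid = (0.5, 2.5, 3.0, 4.5)
    results = {}
    for S in grid:
        per_image = []
        for img, truth, params in sim_dataset:
            cfg = SegmentationConfig(cut=CutConfig(S=S))
            res = segment_image(img, cfg)
            scores = evaluate_detection(
                res.centroids, truth.centroids, radius=params.cell_radius[0]
            )
            per_image.append((scores, res.n_cells))
        results[S] = per_image
    return results
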