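"""Shared fixtures: phantom datasets and (session-scoped) trained models.

Training the desk-scale networks takes a couple of minutes, so the trained
handles are built once per session and shared by every test that needs them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import eatquant as eq

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from eatquant.classifier import ClassifierConfig, train_classifier
from eatquant.segmenter import SegmenterConfig, train_segmenter

TRAIN_GRID = 96  # native phantom grid for the desk-scale learning experiments


@pytest.fixture(scope="session")
def train_cohort():
    """12 phantoms (grid 96): per-slice images, labels, and (image, mask) pairs."""
    specs = eq.generate_phantom_cohort(12, seed=11, grid_size=TRAIN_GRID)
    images, labels, seg_imgs, seg_masks = [], [], [], []
    for sp in specs:
        series, masks, gt = eq.generate_phantom_series(sp)
        for s, m, y in zip(series, masks, gt.slice_labels):
            images.append(s.pixels)
            labels.append(int(y))
            if y:
                seg_imgs.append(s.pixels)
                seg_masks.append(m.grid)
    return {
        "images": images,
        "labels": np.array(labels),
        "seg_imgs": seg_imgs,
        "seg_masks": seg_masks,
    }


@pytest.fixture(scope="session")
def trained_classifier(train_cohort):
    cfg = ClassifierConfig(
        epochs=30, batch_size=32, lr=1e-3, input_size=48, width=8, n_stages=3, seed=7
    )
    return train_classifier(train_cohort["images"], train_cohort["labels"], cfg)


@pytest.fixture(scope="session")
def trained_segmenter(train_cohort):
    cfg = SegmenterConfig(
        epochs=20, batch_size=8, lr=3e-3, lr_decay_after=10,
        input_size=64, base_filters=8, depth=2, seed=9,
    )
    return train_segmenter(train_cohort["seg_imgs"], train_cohort["seg_masks"], cfg)


@pytest.fixture(scope="session")
def eval_cohort():
    """30 held-out phantoms (grid 96) with their analytic ground truths."""
    specs = eq.generate_phantom_cohort(30, seed=77, grid_size=TRAIN_GRID)
    cohort, truths = [], {}
    for sp in specs:
        series, masks, gt = eq.generate_phantom_series(sp)
        cohort.append(series)
        truths[series.patient_id] = (masks, gt)
    return cohort, truths


@pytest.fixture()
def noiseless_spec():
    return eq.PhantomSpec(
        n_slices=10, eat_slice_range=(3, 8), grid_size=128,
        noise_sd=0.0, eat_hu_sd=0.0, eat_hu_mean=-110.0, seed=3,
    )
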