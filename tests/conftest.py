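"""Shared fixtures.

Heavy artifacts (the default 60-plant synthetic dataset and the
grid-searched model trained on it) are session-scoped so the whole suite
pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from rootspec import (
    SceneConfig,
    build_optics,
    calibrate,
    grid_search,
    grow_scene,
    partition_grid,
    render_scene,
    root_mask_from_cube,
    split_train_test,
    trim_bands,
)
from rootspec.pipeline import frame_to_table, simulate_dataset

DATASET_SEED = 11
SPLIT_SEED = 5


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    return SceneConfig()


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A quarter-field single-plant scene for cheap per-test rendering."""
    return SceneConfig(image_size_px=(256, 256), field_cm=(12.5, 12.5), n_plants=2)


@pytest.fixture(scope="session")
def optics(default_config):
    return build_optics(default_config.wavelengths_nm)


@pytest.fixture(scope="session")
def small_scene(small_config):
    """One rendered small scene with its calibrated, trimmed cube."""
    optics = build_optics(small_config.wavelengths_nm)
    arch, labels = grow_scene(small_config, [0.9, 0.5], seed=42)
    raw = render_scene(arch, optics, small_config, seed=42, plant_labels=labels)
    cube = trim_bands(calibrate(raw))
    return raw, cube


@pytest.fixture(scope="session")
def dataset():
    """The default 60-plant training dataset (study conditions)."""
    frame, wavelengths = simulate_dataset(60, seed=DATASET_SEED)
    return frame, wavelengths


@pytest.fixture(scope="session")
def train_test(dataset):
    frame, wavelengths = dataset
    train, test = split_train_test(frame, train_frac=0.8, seed=SPLIT_SEED)
    return frame_to_table(train, wavelengths), frame_to_table(test, wavelengths), train, test


@pytest.fixture(scope="session")
def searched_model(train_test):
    """Grid-searched PLSR model over all 36 preprocessing specs."""
    train_table, _, _, _ = train_test
    model, cv, ranking = grid_search(train_table, max_lv=16)
    return model, cv, ranking


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
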