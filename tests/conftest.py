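"""Shared fixtures: canonical scenes and a trained shape model.

Scene generation and model training are deterministic, so session scope is
safe and keeps the suite fast.
"""

import numpy as np
import pytest

from blobslice.filtering import dog_filter
from blobslice.slices import segment_all_slices
from blobslice.synthetic_data import (
    default_benchmark_spec,
    default_config,
    generate_scene,
    train_default_model,
)


@pytest.fixture(scope="session")
def benchmark_scene():
    return generate_scene(default_benchmark_spec())


@pytest.fixture(scope="session")
def benchmark_config(benchmark_scene):
    return default_config(benchmark_scene.spec).with_spacing(benchmark_scene.spacing)


@pytest.fixture(scope="session")
def benchmark_filtered(benchmark_scene, benchmark_config):
    return dog_filter(benchmark_scene.volume, benchmark_config)


@pytest.fixture(scope="session")
def benchmark_slices(benchmark_scene, benchmark_filtered, benchmark_config):
    return segment_all_slices(benchmark_scene.volume, benchmark_filtered, benchmark_config)


@pytest.fixture(scope="session")
def shape_model():
    return train_default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
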