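"""Shared fixtures: tiny scenes, tiny models, random-mask helpers."""

import numpy as np
import pytest

from leafseg import DatasetSplit, SceneSpec, SceneType, generate_sample
from leafseg.network import CompositeSegNet, tiny_model_config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_samples(image_size: int, n: int = 4):
    types = [
        SceneType.NORMAL,
        SceneType.SPOTTED_LESIONS,
        SceneType.OCCLUDED,
        SceneType.UNEVEN_ILLUMINATION,
        SceneType.REGIONAL_LESIONS,
    ]
    return [
        generate_sample(
            SceneSpec(scene_type=types[i % len(types)], image_size=image_size,
                      rng_seed=i)
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def samples32():
    return make_samples(32, 4)


@pytest.fixture(scope="session")
def samples64():
    return make_samples(64, 4)


@pytest.fixture(scope="session")
def split32(samples32):
    return DatasetSplit(train=samples32, test=samples32)


@pytest.fixture()
def tiny_model32():
    return CompositeSegNet(tiny_model_config(input_size=32, seed=7))


def random_binary_mask(rng, h, w, p=0.5):
    return (rng.random((h, w)) < p).astype(np.uint8)
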