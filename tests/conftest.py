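import warnings
from dataclasses import replace

import numpy as np
import pytest

from rootlapse.simulate import (
    HairSimParams,
    PunctaSimParams,
    generate_hair_timelapse,
    preset,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def tiny_hair_params() -> HairSimParams:
    """A short, small-field hair simulation for fast unit tests."""
    return replace(
        preset("control", seed=11),
        n_hairs=5,
        record_duration_min=320.0,
        initiation_window=(0.0, 80.0),
        field_beyond_root_um=320.0,
    )


@pytest.fixture(scope="session")
def tiny_hair_data(tiny_hair_params):
    return generate_hair_timelapse(tiny_hair_params)


@pytest.fixture(scope="session")
def tiny_puncta_params() -> PunctaSimParams:
    """A small flat-profile puncta simulation for fast unit tests."""
    return PunctaSimParams(
        region_layout=((20.0, "hair"), (20.0, "non_hair")),
        file_length_um=80.0,
        duration_min=90.0,
        flat_profile=True,
        seed=21,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
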