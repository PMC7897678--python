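import numpy as np
import pytest

from synaptoquant import ColocPlanEntry, SceneSpec, SpotSet


@pytest.fixture
def small_noiseless_spec():
    """Tiny noiseless single-channel scene with well-separated spots."""
    return SceneSpec(
        field_size_nm=(6400.0, 6400.0, 3000.0),
        channels=("a",),
        n_spots_per_channel={"a": 20},
        background_level=0.0,
        noise_sd=0.0,
        min_separation_sigma=4.0,
        seed=123,
    )


@pytest.fixture
def paired_spec():
    """Two-channel scene with half of channel A given a coincident partner."""
    return SceneSpec(
        channels=("a", "b"),
        n_spots_per_channel={"a": 200, "b": 200},
        coloc_plan=(ColocPlanEntry("a", "b", 0.5, 0.0),),
        seed=7,
    )


def uniform_spots(rng, n, field_size_nm, channel=""):
    return SpotSet.from_coords(
        rng.uniform(0.0, field_size_nm, size=(n, 3)), field_size_nm, channel
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
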