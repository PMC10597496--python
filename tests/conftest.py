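"""Shared fixtures.

The session-scoped Base-model ground truth run is deliberately short
(20,000 ms) — enough spikes for frame libraries and metric checks while
keeping the default suite fast.  All fixtures are seeded.
"""

import numpy as np
import pytest

from onevent.experiments import build_frame_libraries
from onevent.point_models import load_model


@pytest.fixture(scope="session")
def base_model():
    return load_model("base")


@pytest.fixture(scope="session")
def wb_model():
    return load_model("wb")


@pytest.fixture(scope="session")
def base_ground_truth():
    """(trace, random_library, spiking_library) for Base, 20 s, seeded."""
    base = load_model("base")
    return build_frame_libraries(base, duration=20_000.0, k_random=2_000,
                                 seed=20240901)


@pytest.fixture(scope="session")
def base_trace(base_ground_truth):
    return base_ground_truth[0]


@pytest.fixture(scope="session")
def base_random_frames(base_ground_truth):
    return base_ground_truth[1]


@pytest.fixture(scope="session")
def base_spiking_frames(base_ground_truth):
    lib = base_ground_truth[2]
    assert lib is not None, "seeded 20 s Base run should spike"
    return lib
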