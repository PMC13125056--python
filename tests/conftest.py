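"""Shared fixtures: one small synthetic experiment reused across modules."""

import numpy as np
import pytest

from midvision.design import SplitSpec, make_design
from midvision.simulate import (
    ForwardModelSpec,
    simulate_annotations,
    simulate_eeg,
)


@pytest.fixture(scope="session")
def small_design():
    """5 rooms (2 held out) x 6 actions x 3 characters x 4 cameras = 360."""
    return make_design(5, 6, 3, 4, SplitSpec(n_heldout_rooms=2), seed=7)


@pytest.fixture(scope="session")
def small_annotations(small_design):
    return simulate_annotations(small_design, seed=11)


@pytest.fixture(scope="session")
def small_forward_spec():
    return ForwardModelSpec(reps={"train": 4, "test": 6, "validation": 4}, seed=13)


@pytest.fixture(scope="session")
def small_eeg(small_design, small_annotations, small_forward_spec):
    return simulate_eeg(small_design, small_annotations, small_forward_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
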