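"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ddcq import ModelSpec, SimulationConfig, simulate_dataset


def make_dataset(seed=0, hypothesis="null", **overrides):
    """One simulated dataset under the benchmark design (overridable)."""
    cfg = SimulationConfig(seed=None, **overrides)
    return simulate_dataset(cfg, hypothesis, np.random.default_rng(seed))


@pytest.fixture
def dataset():
    return make_dataset(seed=0)


@pytest.fixture
def alt_dataset():
    return make_dataset(seed=1, hypothesis="alternative")


@pytest.fixture
def default_spec():
    return ModelSpec()


@pytest.fixture
def ml_pooled_spec():
    return ModelSpec(criterion="ML", residual_variance="pooled")
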