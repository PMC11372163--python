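"""Shared fixtures: small simulated conditions and segmentation plans."""

import numpy as np
import pytest

import biqpc as bq

# Q_I exemplar carriers from the study's frequency set
F1 = 120.0 / (2.0 * np.pi)
F2 = 70.0 / (2.0 * np.pi)
F3 = 80.0 / (2.0 * np.pi)


@pytest.fixture(scope="session")
def plan() -> bq.SegmentPlan:
    return bq.SegmentPlan(fs=100.0, segment_length=500)


@pytest.fixture(scope="session")
def default_condition() -> bq.ConditionSpec:
    return bq.ConditionSpec(F1=F1, F2=F2, F3=F3, W=0.05, n_epochs=128, seed=7)


@pytest.fixture(scope="session")
def default_series(default_condition) -> bq.EpochedSeries:
    return bq.simulate_condition(default_condition)


@pytest.fixture(scope="session")
def small_series() -> bq.EpochedSeries:
    cond = bq.ConditionSpec(F1=F1, F2=F2, F3=F3, W=0.3, n_epochs=16, seed=3)
    return bq.simulate_condition(cond)


def gaussian_series(seed: int, n_epochs: int = 16, n_samples: int = 500) -> bq.EpochedSeries:
    """Three independent white-noise channels (a fully null record)."""
    rng = np.random.default_rng(seed)
    return bq.EpochedSeries(data=rng.normal(size=(3, n_epochs, n_samples)), fs=100.0)
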