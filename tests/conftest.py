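import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from rivaltouch.config import PipelineConfig, SimConfig
from rivaltouch.preprocess import clean_trace
from rivaltouch.simulate import simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

TWO_CONDITIONS = ("parallel_aligned_visible", "orthogonal_aligned")
EFFECT_ON = frozenset({"parallel_aligned_visible"})


def small_config(**kw) -> SimConfig:
    base = dict(
        n_participants=6,
        n_fast=2,
        n_trials_per_condition=6,
        conditions=TWO_CONDITIONS,
        effect_conditions=EFFECT_ON,
        seed=17,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def null_dataset():
    """Small dataset with no tactile effect (both hazard multipliers 1)."""
    cfg = small_config()
    traces, events = simulate_dataset(cfg)
    return cfg, traces, events


@pytest.fixture(scope="session")
def effect_dataset():
    """Small dataset with a strong congruency effect in one condition."""
    cfg = small_config(
        hazard_mult_congruent=0.4, hazard_mult_incongruent=3.0, seed=23
    )
    traces, events = simulate_dataset(cfg)
    return cfg, traces, events


@pytest.fixture(scope="session")
def clean_null_dataset(null_dataset):
    cfg, traces, events = null_dataset
    return cfg, [clean_trace(tr) for tr in traces], events


@pytest.fixture(scope="session")
def clean_effect_dataset(effect_dataset):
    cfg, traces, events = effect_dataset
    return cfg, [clean_trace(tr) for tr in traces], events


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
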