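"""Shared fixtures: small synthetic stimulus sets and recordings."""

import logging

import numpy as np
import pytest

from vocdisc import (
    CrossValPlan,
    StimulusSet,
    generate_population,
    generate_vocalization_set,
    simulate_responses,
)
from vocdisc.stimuli import StimulusTemplate

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def full_stimuli():
    """The default 11-call synthetic set (session-cached; deterministic)."""
    return generate_vocalization_set(seed=1)


@pytest.fixture(scope="session")
def small_stimuli(full_stimuli):
    """First four calls of the default set, for fast classification tests."""
    return StimulusSet(full_stimuli.stimuli[:4], full_stimuli.trial_length,
                       full_stimuli.intensity_db)


@pytest.fixture(scope="session")
def small_recording(small_stimuli):
    """Six tonotopically spread units, 20 trials of the 4-call set."""
    pop = generate_population("linear_double_shank", 6, (0.5, 12.0), seed=3)
    return simulate_responses(pop, small_stimuli, n_trials=20, seed=5)


@pytest.fixture(scope="session")
def noisy_recording(small_stimuli):
    """Same geometry with strong shared (common-input) noise, c = 0.5."""
    pop = generate_population("linear_double_shank", 6, (0.5, 12.0), seed=3,
                              shared_noise_c=0.5)
    return simulate_responses(pop, small_stimuli, n_trials=10, seed=5)


@pytest.fixture(scope="session")
def am_band_stimuli():
    """2 carrier bands x 3 AM rates: spectral and temporal class structure.

    Calls sharing a band have identical mean rates and drive the same
    units; only the AM timing distinguishes them.
    """
    templates = [
        StimulusTemplate(f"b{b}_am{int(am)}", 0.9, ((lo, hi),), am_rate=am)
        for b, (lo, hi) in enumerate([(200.0, 1200.0), (3000.0, 9000.0)])
        for am in (10.3, 15.4, 24.0)
    ]
    return generate_vocalization_set(templates, seed=2)


@pytest.fixture
def plan():
    return CrossValPlan(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
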