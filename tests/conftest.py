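import numpy as np
import pytest

from taskspike.simulate import (
    SimConfig,
    cohort_specs,
    projection_specs,
    simulate_behavior,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact session (120 trials, 2 neurons per archetype, 3 stimulated
    neurons) with ground truth."""
    specs = cohort_specs(n_per_type=2) + projection_specs(2, 1, seed=11)
    cfg = SimConfig(seed=11, n_trials_target=120, pedal_sample_rate=200,
                    neuron_specs=specs)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def behavior_320():
    """A long self-paced session's trial table and pedal traces."""
    cfg = SimConfig(seed=21, n_trials_target=320, pedal_sample_rate=200)
    trials, traces = simulate_behavior(cfg)
    return cfg, trials, traces


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
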