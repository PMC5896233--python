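import numpy as np
import pytest

from headvel.stimuli import make_rotation_stimulus
from headvel.synthetic import TuningSpec, simulate_population, simulate_vm_trial


@pytest.fixture(scope="session")
def stim_fast():
    """Compact full-geometry stimulus (1 ms grid, short padding)."""
    return make_rotation_stimulus(90.0, 80.0, n_periods=1, pre_s=0.5,
                                  post_s=0.5, dt=1e-3)


@pytest.fixture(scope="session")
def stim_baseline():
    """Stimulus with the full 2-s stationary baseline window."""
    return make_rotation_stimulus(90.0, 80.0, n_periods=1, pre_s=2.0,
                                  post_s=0.5, dt=1e-3)


@pytest.fixture(scope="session")
def population348():
    """Default calibrated 348-trial / 8-neuron population (fixed seed)."""
    return simulate_population(n_trials=348, n_neurons=8, seed=42)


@pytest.fixture()
def on_trials(stim_baseline):
    """Ten noisy trials of a clockwise-preferring cell."""
    spec = TuningSpec(gain_cw=0.06, gain_ccw=0.02, noise_sd=1.5)
    rng = np.random.default_rng(7)
    return [simulate_vm_trial(stim_baseline, spec, seed=rng,
                              insert_spikes=False, trial_index=i)
            for i in range(10)]
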