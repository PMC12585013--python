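import numpy as np
import pytest

from lnkit.synth import (
    GroundTruthNeuron,
    biphasic_filter,
    gen_fullfield_noise,
    gen_ln_spikes,
)


@pytest.fixture(scope="session")
def std_neuron():
    """A well-behaved LN-Poisson ground-truth neuron."""
    return GroundTruthNeuron(
        true_filter=biphasic_filter(),
        nl_slope=30.0,
        nl_threshold=0.2,
        baseline_rate=2.0,
    )


@pytest.fixture(scope="session")
def noise_15min():
    """Fifteen minutes of binary full-field noise at 60 FPS."""
    return gen_fullfield_noise(900.0, seed=3)


@pytest.fixture(scope="session")
def ln_recording(std_neuron, noise_15min):
    """(stimulus, spikes) from the standard neuron over 15 min of noise."""
    spikes = gen_ln_spikes(noise_15min, std_neuron, seed=3)
    return noise_15min, spikes


@pytest.fixture(scope="session")
def short_noise():
    """Five minutes of binary noise for cheaper round trips."""
    return gen_fullfield_noise(300.0, seed=11)


def naive_sta(spike_frames, stim_values, n_lags):
    """Brute-force spike-triggered mean: one explicit loop per spike."""
    acc = np.zeros(n_lags)
    count = 0
    for f in spike_frames:
        if f < n_lags - 1:
            continue
        for k in range(n_lags):
            acc[k] += stim_values[f - k]
        count += 1
    return acc / count, count
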