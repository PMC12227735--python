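import numpy as np
import pytest

from vtaephys import NeuronSimSpec, SpikeTrain, simulate_neuron


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stationary_train():
    """One stationary gamma-renewal train: 300 s baseline + 180 s tail."""
    spec = NeuronSimSpec(baseline_rate_hz=5.0, isi_shape=2.0)
    return simulate_neuron(
        spec, epoch=(0.0, 480.0), injection_times=(300.0,),
        rng=np.random.default_rng(7), neuron_id="stat",
    )


@pytest.fixture
def regular_train():
    """Perfectly regular 2 Hz train over 300 s."""
    return SpikeTrain("reg", np.arange(0.25, 300.0, 0.5), 0.0, 300.0)
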