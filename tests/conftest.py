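import numpy as np
import pytest

from convallis.core_sim import Network, NeuronParams, SynapseGroup


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return NeuronParams()


def single_neuron_net(weight=1.0, delay=0.1, reversal="excitatory",
                      params=None, n_inputs=1):
    """One LIF neuron driven by external input channels."""
    net = Network(n_neurons=1, n_inputs=n_inputs, params=params or NeuronParams())
    net.add_group(SynapseGroup(
        source_ids=np.zeros(1, dtype=int), target_ids=np.zeros(1, dtype=int),
        weights=[weight], delays=[delay], reversal_class=reversal,
        source_kind="input",
    ))
    return net


@pytest.fixture
def noisy_voltage_trace(rng):
    """A wandering subthreshold voltage trace, 2 s at 0.1 ms."""
    n = 20000
    v = -70 + 8 * np.sin(np.arange(n) * 0.003) + rng.normal(0, 2, n).cumsum() * 0.01
    return np.clip(v, -80, -45)
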