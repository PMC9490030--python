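import numpy as np
import pytest

from spikecollide.simulate import Projection, SimConfig, SimNeuron, SpikeTemplate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_projection_config(
    latency: float = 10.0,
    jitter_sd: float = 0.05,
    rate: float = 20.0,
    noise_sd: float = 1.0,
    n_anti: int = 60,
    session_length: float = 150.0,
    amp=(-30.0, -12.0, -6.0, -2.0),
) -> SimConfig:
    """One projection neuron on one tetrode, one stimulation site."""
    neuron = SimNeuron(
        id=0,
        tetrode_id=0,
        amp_pattern=np.asarray(amp),
        template=SpikeTemplate(0.7),
        rate=rate,
        r=2.8,
        projections=[Projection(site=0, d=0.7, C=latency - 0.7, jitter_sd=jitter_sd)],
        label="projection",
    )
    return SimConfig(
        neurons=[neuron],
        sites=[0],
        n_tetrodes=1,
        session_length=session_length,
        n_anti=n_anti,
        noise_sd=noise_sd,
    )
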