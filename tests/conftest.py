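import numpy as np
import pytest

from navloop import synthetic as syn


@pytest.fixture(scope="session")
def cond72():
    return syn.PH_CONDITIONS[7.2]


@pytest.fixture(scope="session")
def channel72(cond72):
    return syn.channel_from_densities(
        cond72.peak_density_pa_pf,
        cond72.persistent_density_pa_pf,
        cond72.act,
        cond72.inact,
        protocol=syn.make_activation_protocol(10),
    )


@pytest.fixture(scope="session")
def cell():
    return syn.CellModel()


@pytest.fixture(scope="session")
def noiseless_act_rec(channel72, cell):
    return syn.simulate_recording(
        channel72, cell, syn.make_activation_protocol(10), syn.NoiseModel(0.0, 1)
    )


@pytest.fixture(scope="session")
def noiseless_inact_rec(channel72, cell):
    return syn.simulate_recording(
        channel72, cell, syn.make_inactivation_protocol(10), syn.NoiseModel(0.0, 2)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
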