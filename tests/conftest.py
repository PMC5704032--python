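import pytest

import twinquad as tq


@pytest.fixture(scope="session")
def default_config():
    return tq.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def reference(default_config):
    return tq.generate_reference(
        default_config, tq.rng_streams(default_config.seed)[0]
    )


@pytest.fixture(scope="session")
def sim(default_config, reference):
    """Noiseless quad at the default (desk-scale) study conditions."""
    return tq.simulate_quad(
        default_config, reference, tq.rng_streams(default_config.seed)[1]
    )


@pytest.fixture(scope="session")
def simdir(tmp_path_factory, default_config, reference, sim):
    """The default simulation written to disk (manifest path returned)."""
    outdir = tmp_path_factory.mktemp("quad")
    return tq.write_simulation(reference, sim, default_config, outdir)
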