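import pytest

from cdisoflux.double_spike import IsotopeSystem
from cdisoflux.synthetic import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def system() -> IsotopeSystem:
    return IsotopeSystem.default()


@pytest.fixture(scope="session")
def noise_free_run():
    cfg = SimConfig(noise_delta_2sd=0.0, noise_conc_rel=0.0)
    return cfg, simulate_experiment(cfg, seed=11)


@pytest.fixture(scope="session")
def default_run():
    cfg = SimConfig()
    return cfg, simulate_experiment(cfg, seed=11)
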