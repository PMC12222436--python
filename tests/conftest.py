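import numpy as np
import pytest

from cpue_ssm import inference, model, synthetic
from cpue_ssm.sampler import SamplerConfig

DEMO_SEED = 42
DEMO_FIT_SEED = 11


@pytest.fixture(scope="session")
def demo_sim():
    cfg = synthetic.group_structured_config()
    return cfg, synthetic.simulate_community(cfg, DEMO_SEED)


@pytest.fixture(scope="session")
def demo_prepared(demo_sim):
    cfg, syn = demo_sim
    return model.prepare(syn.panel, period4_starts=dict(cfg.period4_starts))


@pytest.fixture(scope="session")
def demo_fit(demo_prepared):
    """One reduced-schedule fit of the demo panel, shared across tests."""
    return inference.fit(
        demo_prepared,
        sampler_config=SamplerConfig(n_chains=4, n_warmup=500, n_draws=2000),
        seed=DEMO_FIT_SEED,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
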