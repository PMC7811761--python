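import numpy as np
import pytest
from hypothesis import settings

import timascan as t

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_tree():
    return t.default_timascan_tree()


@pytest.fixture(scope="session")
def gated_sample(default_tree):
    """One well-separated 50k-event sample, gated, with truth labels."""
    sample = t.simulate_sample(t.default_sample_spec(
        "fixture", 50_000, seed=42,
        gfap_nonclassical=0.10, gfap_intermediate=0.02,
        plp1_nonclassical=0.03, plp1_intermediate=0.01))
    gating = t.apply_gate_tree(sample, default_tree)
    return sample, gating


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
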