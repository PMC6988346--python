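import numpy as np
import pytest

from tepirna.synth import SynthConfig, make_te_references


@pytest.fixture(scope="session")
def cfg():
    return SynthConfig(seed=7, n_families=3, te_length_range=(1500, 4000))


@pytest.fixture(scope="session")
def te_refs(cfg):
    return make_te_references(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
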