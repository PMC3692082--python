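import numpy as np
import pytest

import comir
from comir import Channel, FixtureSpec, generate_fixture
from comir.pipeline import train_on_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study shared by read-only tests."""
    return generate_fixture(FixtureSpec(n_genes=40, n_mirnas=8, seed=11))


@pytest.fixture(scope="session")
def small_model(small_bundle):
    return train_on_bundle(small_bundle, seed=11)


@pytest.fixture(scope="session")
def small_result(small_bundle, small_model):
    imported = {
        Channel.PITA_DDG: small_bundle.pita_sites,
        Channel.MIRSVR: small_bundle.mirsvr_sites,
    }
    return comir.run(
        small_bundle.targets,
        small_bundle.mirna_sequences,
        small_bundle.expression,
        small_model,
        imported=imported,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
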