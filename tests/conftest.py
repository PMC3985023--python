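import pytest

from ppma.synthetic_fixtures import (
    make_gamma_ca_fixture,
    make_translation_fixture,
    make_replay_collection,
)


@pytest.fixture(scope="session")
def replay():
    return make_replay_collection(seed=7)


@pytest.fixture(scope="session")
def translation_fx():
    return make_translation_fixture()


@pytest.fixture(scope="session")
def gamma():
    return make_gamma_ca_fixture(seed=11)
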