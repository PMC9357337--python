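import pytest

import pathko as pk


@pytest.fixture(scope="session")
def toy_net() -> pk.PathwayNetwork:
    return pk.toy_pathway()


@pytest.fixture(scope="session")
def toy_profs() -> dict[str, pk.ExpressionProfile]:
    return pk.toy_profiles()


@pytest.fixture(scope="session")
def config() -> pk.ModelConfig:
    return pk.ModelConfig()


ABSTRACT = "WNT_PCP_PATHWAY"


@pytest.fixture(scope="session")
def toy_abstract() -> str:
    return ABSTRACT
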