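import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def uzpo():
    from paleomt.haplotypes import ancient_population

    return ancient_population("aUzPo")


@pytest.fixture(scope="session")
def boo():
    from paleomt.haplotypes import ancient_population

    return ancient_population("aBOO")


@pytest.fixture(scope="session")
def fixture_individuals():
    from paleomt.haplotypes import load_ancient_fixture

    return load_ancient_fixture()
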