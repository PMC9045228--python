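import pytest

from shufflon import GeneratorConfig, generate_locus, tp114_like_model


@pytest.fixture(scope="session")
def model4():
    return tp114_like_model(4)


@pytest.fixture(scope="session")
def locus_and_truth():
    """One TP114-like synthetic locus shared across the suite."""
    return generate_locus(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def locus(locus_and_truth):
    return locus_and_truth[0]


@pytest.fixture(scope="session")
def truth(locus_and_truth):
    return locus_and_truth[1]
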