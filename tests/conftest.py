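import pytest

from screendca.simulate import SyntheticConfig, fixture_table, generate


@pytest.fixture(scope="session")
def table5():
    """The printed screening 2x2: TP=166, FP=267, FN=78, TN=502."""
    return fixture_table("table5_2x2")


@pytest.fixture(scope="session")
def big_cohort():
    """Default-parameter synthetic cohort, large enough for LLN checks."""
    return generate(SyntheticConfig(n=100_000, seed=123))


@pytest.fixture(scope="session")
def big_config():
    return SyntheticConfig(n=100_000, seed=123)
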