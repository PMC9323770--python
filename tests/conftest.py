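import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tokamachi():
    from mudgas import datasets

    return datasets.load_tokamachi()


@pytest.fixture(scope="session")
def murono(tokamachi):
    return [r for r in tokamachi if r.site == "Murono"]


@pytest.fixture(scope="session")
def noiseless_scenario():
    from mudgas.synth import ScenarioConfig

    return ScenarioConfig(seed=11, n_samples=12, sigma_bulk=0.0, sigma_offset=0.0)
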