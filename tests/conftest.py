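import pytest

from rhizotyper.synthetic_data import make_characterization_fixture, random_genome


@pytest.fixture(scope="session")
def characterization_fixture():
    """One 200 kb genome with planted IS copies, CRISPR array and oriC."""
    return make_characterization_fixture(seed=1)


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(50_000, seed=42)
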