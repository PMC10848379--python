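import pytest

from mitorearr import reference


@pytest.fixture(scope="session")
def annotation():
    """Packaged 38-feature porcelain-crab annotation (no sequence)."""
    return reference.load_annotation()


@pytest.fixture(scope="session")
def composition_table():
    return reference.load_composition_table()


@pytest.fixture(scope="session")
def codon_counts_table():
    return reference.load_codon_counts()


@pytest.fixture(scope="session")
def ground_pattern():
    return reference.ground_pattern_order()


@pytest.fixture(scope="session")
def observed_order():
    return reference.observed_order()


@pytest.fixture(scope="session")
def published_scenario():
    return reference.published_scenario()
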