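import pytest

from thioqsar.activity import load_activity_table
from thioqsar.datasets import load_compound_structures
from thioqsar.synthetic import generate_toy_molecules


@pytest.fixture(scope="session")
def compounds():
    """The 21 packaged thiosemicarbazone structures."""
    return load_compound_structures()


@pytest.fixture(scope="session")
def activity_df():
    return load_activity_table()


@pytest.fixture(scope="session")
def toyset():
    """25 seeded toy molecules with oracle-verified descriptor values."""
    return generate_toy_molecules(25, seed=7)
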