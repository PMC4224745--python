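import pytest

from vegscreen import MutableTemplate, load_fixtures, parse_peptide

TEMPLATE = "QKRKRKKSRYKS"
CORE = "RKRKKSR"
MUTABLE = (1, 2, 10, 11, 12)


@pytest.fixture(scope="session")
def core():
    return parse_peptide(CORE)


@pytest.fixture(scope="session")
def template():
    return MutableTemplate.from_sequences(TEMPLATE, CORE, MUTABLE)


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()
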