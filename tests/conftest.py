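import pytest

from rrbsdesign.catalog import EnzymeSpec, IsoschizomerFamily
from rrbsdesign.genome import GenomeSequence


@pytest.fixture
def mspi():
    return EnzymeSpec("MspI", "CCGG", 1)


@pytest.fixture
def fam_mspi(mspi):
    return IsoschizomerFamily("fam_MspI", (mspi,))


@pytest.fixture
def toy_genome():
    """One chromosome 'CCGGAACCGG' -> MspI cuts at 1 and 7."""
    return GenomeSequence.from_dict("toy", {"chr1": "CCGGAACCGG"})


@pytest.fixture(scope="session")
def scene():
    """The seeded ~150 kb standard fixture shared across slow tests."""
    from rrbsdesign.fixtures import standard_fixture

    return standard_fixture(7)
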