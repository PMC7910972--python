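import numpy as np
import pytest

from ltrkit.synthetic_data import make_filter_fixture, make_profiles


@pytest.fixture(scope="session")
def small_profiles():
    """Four-lineage profile set spanning both superfamilies."""
    return make_profiles(
        ["ATHILA", "REINA", "SIRE", "TORK/TAR"], seed=11, length_range=(5000, 8000)
    )


@pytest.fixture(scope="session")
def filter_fixture():
    """The 12-element curation fixture: 7 intact + one per defect class."""
    return make_filter_fixture(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
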