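import numpy as np
import pytest

from rnaed.fileio import FixtureSpec, make_fixture
from rnaed.seqcore import ConstraintSpec
from rnaed.thermo.model import EnergyModel


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def constraint_spec():
    return ConstraintSpec()


@pytest.fixture(scope="session")
def small_transcript():
    """~195-nt transcript with 3 embedded motifs; shared across modules."""
    return make_fixture(
        FixtureSpec(cds_codons=40, utr5_len=40, utr3_len=35, n_motifs=3, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))
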