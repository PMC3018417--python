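import numpy as np
import pytest

from phytodesk.seqcore import AMINO_ACID, NUCLEOTIDE, BioSequence, build_fullmat


@pytest.fixture(scope="session")
def nt_matrix():
    return build_fullmat(NUCLEOTIDE)


@pytest.fixture(scope="session")
def aa_matrix():
    return build_fullmat(AMINO_ACID)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_nt(rng, length: int, name: str = "seq") -> BioSequence:
    return BioSequence(
        name, "".join(rng.choice(list("ACGT"), size=length)), NUCLEOTIDE
    )
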