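import numpy as np
import pytest

from actmap.refseq import CodingSequence
from actmap.screen import AlignedRead
from actmap.simulate import random_coding_sequence


@pytest.fixture
def toy_cds():
    return CodingSequence("toy", "ATGGCT")


@pytest.fixture(scope="session")
def ref120():
    """Fixed 120-codon synthetic reference used across screen tests."""
    return random_coding_sequence(120, seed=123)


@pytest.fixture(scope="session")
def ref50():
    """The scaled-down screen reference: 50 sense codons (153 nt).

    At 5,000 reads/pool a 150-base read tiles this reference almost
    fully, keeping every residue's expected mutant count in the regime
    of a deeply sequenced screen.
    """
    return random_coding_sequence(50, seed=123)


def make_read(cds, ref_start, bases, quals=40, read_id="r", indel=False):
    """Build an AlignedRead with scalar or per-base qualities."""
    if np.isscalar(quals):
        quals = np.full(len(bases), quals, dtype=np.int16)
    return AlignedRead(
        read_id=read_id,
        ref_start=ref_start,
        bases=bases,
        quals=np.asarray(quals, dtype=np.int16),
        indel_or_clip=indel,
    )


@pytest.fixture
def read_factory():
    return make_read
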