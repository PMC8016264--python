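import numpy as np
import pytest

from mitorec.genotypes import GenotypeVector, MarkerMap
from mitorec.simulate import SyntheticConfig, gen_marker_map

BASE_N = "A"
BASE_P = "C"


def make_map(positions, focal=None):
    """Small hand-built marker map for classifier/tract tests."""
    n = len(positions)
    if focal is None:
        focal = (n // 2, n // 2 + 1) if n // 2 + 1 < n else (n - 2, n - 1)
    return MarkerMap(
        marker_id=tuple(f"M{i + 1}" for i in range(n)),
        chromosome="chr1",
        position=tuple(positions),
        allele_n=(BASE_N,) * n,
        allele_p=(BASE_P,) * n,
        focal_markers=focal,
    )


def gv(states, sample_id="s"):
    return GenotypeVector(sample_id, tuple(states))


@pytest.fixture(scope="session")
def map15():
    """The standard synthetic 15-marker ~445 kb map."""
    return gen_marker_map(SyntheticConfig(), seed=0)


@pytest.fixture(scope="session")
def dense_map6():
    """6 markers 1 kb apart: every possible tract is far below 100 kb."""
    return make_map([1000 * (i + 1) for i in range(6)])


@pytest.fixture(scope="session")
def sparse_map6():
    """6 markers 150 kb apart: every tract midpoint length exceeds 100 kb."""
    return make_map([150_000 * (i + 1) for i in range(6)])
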