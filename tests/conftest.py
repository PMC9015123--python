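import numpy as np
import pytest

from alnzip.msa_io import msa_from_rows
from alnzip.synthetic import EvolutionParams, generate_msa


@pytest.fixture
def pair_two_runs():
    """Aligned pair differing exactly at columns {2,3,10,11}, i.e. two
    maximal runs of length 2 — the canonical worked example for delta
    costs (store "aa" at 2 and "cc" at 10 to rebuild row 0 from row 1)."""
    s1 = "gtaagtcttaccgt"
    s2 = "gtttgtcttattgt"
    assert [j for j in range(14) if s1[j] != s2[j]] == [2, 3, 10, 11]
    return s1, s2


@pytest.fixture
def small_msa():
    return msa_from_rows(["acgtacgt", "acctacgt", "ac-tacga", "ttttacgt"])


@pytest.fixture
def clustered_msa():
    return generate_msa(
        EvolutionParams(n=40, l=300, substitution_prob=0.01, tree="clustered", seed=11)
    )


def random_msa(rng: np.random.Generator, n: int, l: int, alphabet: str = "acgt-") -> "object":
    chars = np.array(list(alphabet))
    mat = chars[rng.integers(0, len(chars), (n, l))]
    return msa_from_rows(["".join(r) for r in mat])
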