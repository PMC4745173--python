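import itertools

import numpy as np
import pytest

from evoslope.simulate import random_dna

#: The published grouping of all 24 assignment codes into three classes.
EQUIVALENCE_TABLE = {
    1: ["ACGT", "ACTG", "CAGT", "CATG", "GTAC", "GTCA", "TGAC", "TGCA"],
    2: ["AGCT", "AGTC", "GACT", "GATC", "CTAG", "CTGA", "TCAG", "TCGA"],
    3: ["ATCG", "ATGC", "TACG", "TAGC", "CGAT", "CGTA", "GCAT", "GCTA"],
}

ALL_CODES = ["".join(p) for p in itertools.permutations("ACGT")]


@pytest.fixture(scope="session")
def equivalence_table():
    return EQUIVALENCE_TABLE


@pytest.fixture(scope="session")
def all_codes():
    return ALL_CODES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequences():
    """Ten reproducible iid sequences of length 256."""
    return [random_dna(256, seed=100 + i, id=f"rand{i}") for i in range(10)]
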