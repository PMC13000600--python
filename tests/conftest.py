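import logging

import pytest
from rdkit import RDLogger

from kinfrags.fixtures import (
    FixtureSpec,
    make_mock_bb_set,
    make_syba_corpus,
    make_toy_library,
)
from kinfrags.prefilter import prefilter
from kinfrags.synth import build_bb_index, train_syba

RDLogger.DisableLog("rdApp.*")
logging.getLogger("kinfrags").setLevel(logging.ERROR)

#: the standard toy study conditions used across the suite
STUDY_SPEC = FixtureSpec(
    seed=1,
    pool_sizes={"AP": 16, "FP": 10, "SE": 8, "GA": 8, "B1": 5, "B2": 5},
    pains_fraction=0.12,
    brenk_fraction=0.08,
    ro3_fraction=0.12,
    qed_fraction=0.06,
    syba_fraction=0.1,
    n_duplicates=2,
    n_unfragmented=2,
    n_x_pool=2,
    n_x_only=2,
)
BB_COVERAGE = 0.8


@pytest.fixture(scope="session")
def toy_library():
    return make_toy_library(STUDY_SPEC)


@pytest.fixture(scope="session")
def prefiltered(toy_library):
    library, _ = toy_library
    filtered, report = prefilter(library)
    return filtered, report


@pytest.fixture(scope="session")
def bb_setup(prefiltered):
    library, _ = prefiltered
    blocks, should_pass = make_mock_bb_set(library, BB_COVERAGE, seed=2)
    return build_bb_index(blocks), should_pass


@pytest.fixture(scope="session")
def syba_model():
    easy, hard = make_syba_corpus(3)
    return train_syba(easy, hard)
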