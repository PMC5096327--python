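import numpy as np
import pytest

import idxblast as ib
from idxblast.search_core import SearchParams
from idxblast.synth import SyntheticSpec, generate_database


@pytest.fixture(scope="session")
def default_params():
    return SearchParams()


@pytest.fixture(scope="session")
def small_planted():
    """40-sequence database with 5 planted homolog pairs plus its truth table."""
    spec = SyntheticSpec(n_sequences=40, n_planted=5, seed=3, median_length=150)
    seqs, truth = generate_database(spec)
    return seqs, truth


@pytest.fixture(scope="session")
def small_indexed(small_planted):
    """Sorted database + single-block index over the small planted database."""
    seqs, truth = small_planted
    db = ib.sort_database(seqs)
    blocks = ib.partition_blocks(db, 10**6)
    index = ib.build_database_index(blocks)
    return db, blocks, index, truth


def random_protein(rng: np.random.Generator, length: int) -> ib.ProteinSequence:
    from idxblast.synth import _random_sequence

    return ib.ProteinSequence(f"r{rng.integers(1e9):09d}", "", _random_sequence(rng, length))
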