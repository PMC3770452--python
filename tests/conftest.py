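import numpy as np
import pytest

from homtest import GenotypeTable, ParamPoint


@pytest.fixture
def table1() -> GenotypeTable:
    """The worked real-data example: GABA-A case-control genotype counts."""
    return GenotypeTable(55, 83, 50, 24, 42, 39)


@pytest.fixture
def identical_rows() -> GenotypeTable:
    return GenotypeTable(10, 20, 10, 10, 20, 10)


def random_tables(seed: int, k: int, max_total: int = 200):
    """Random valid genotype tables for property tests."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < k:
        n = int(rng.integers(1, max_total))
        m = int(rng.integers(1, max_total))
        x = rng.multinomial(n, rng.dirichlet(np.ones(3)))
        y = rng.multinomial(m, rng.dirichlet(np.ones(3)))
        out.append(GenotypeTable.from_rows(x, y))
    return out
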