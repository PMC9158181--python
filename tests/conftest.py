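import numpy as np
import pytest

from sorensen_equiv import EnrichmentContingencyTable, EnrichmentProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def moderate_table():
    """n=1000 table with p_hat = (0.125, 0.05, 0.05, 0.775): d_hat = 2/7."""
    return EnrichmentContingencyTable(125, 50, 50, 775)


@pytest.fixture
def high_enrichment_table():
    """Abundant-enrichment table where the normal asymptotics are accurate."""
    return EnrichmentContingencyTable(500, 200, 200, 100)


@pytest.fixture
def small_profile():
    """Four terms, three lists; (a, b) puts one term in each table cell."""
    return EnrichmentProfile.from_columns(
        ["t1", "t2", "t3", "t4"],
        {"a": [1, 1, 0, 0], "b": [1, 0, 1, 0], "c": [1, 1, 1, 0]},
    )


def random_valid_table(rng, n_max=2000):
    """A random contingency table on which the studentized statistic exists."""
    while True:
        n = int(rng.integers(20, n_max))
        p = rng.dirichlet(np.full(4, 0.7))
        n11, n01, n10, n00 = rng.multinomial(n, p)
        if n11 >= 1 and n01 + n10 >= 1:
            return EnrichmentContingencyTable(n11=n11, n10=n10, n01=n01, n00=n00)
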