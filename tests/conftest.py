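import numpy as np
import pytest

from nestsurv.io_data import EncounterHistory


def history(nest="n1", pair="p1", year=2009, renest=0, days=None, codes=None):
    return EncounterHistory(
        nest_id=nest, pair_id=pair, year=year, renest=renest,
        days=np.asarray(days), codes=np.asarray(codes, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fixture():
    """Desk-scale synthetic dataset shared across tests (read-only)."""
    import nestsurv as ns

    return ns.make_default_fixture(42)


@pytest.fixture(scope="session")
def small_dataset(small_fixture):
    import nestsurv as ns

    return ns.fixture_dataset(small_fixture)
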