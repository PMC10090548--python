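import pytest
from hypothesis import HealthCheck, settings

from ccmen import CBETable, SyntheticSpec, generate_cbe_tables, table1_fixture

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture
def toy_cbe():
    """Hand-sized two-receptor CBE table used for hand-checkable enumerations."""
    return CBETable(
        gcc={1: 2.0, 2: 4.0},
        nhc={1: 1.0, 2: 0.5},
        f={1: 1.0, 2: 3.0},
    )


@pytest.fixture
def make_cbe():
    """Factory for seeded synthetic CBE tables of any size."""

    def _make(n=4, seed=0, **kwargs):
        return generate_cbe_tables(SyntheticSpec(n_receptors=n, seed=seed, **kwargs))

    return _make
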