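import pytest

from tsnscan.synthetic_data import (
    SimParams,
    ehh_fixture_matrix,
    qc_toy_matrix,
    simulate_two_pop_sweep,
)

# small, fast study conditions shared across module tests; the full-size
# conditions are exercised by the acceptance suite
SMALL_SIM = dict(N=60, L=1_000_000, m=800, T_split=60, n1=30, n2=30)


@pytest.fixture(scope="session")
def sweep_sim():
    """One small seeded sweep simulation (selection in POP1)."""
    return simulate_two_pop_sweep(SimParams(seed=42, **SMALL_SIM))


@pytest.fixture(scope="session")
def neutral_sim():
    """Matched neutral simulation (s = 0)."""
    return simulate_two_pop_sweep(SimParams(seed=43, s=0.0, **SMALL_SIM))


@pytest.fixture
def ehh_hm():
    return ehh_fixture_matrix()


@pytest.fixture
def qc_hm():
    return qc_toy_matrix()
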