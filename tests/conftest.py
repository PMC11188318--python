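import numpy as np
import pytest

from rxmsm import CodeCatalog
from rxmsm.synthetic_data import SimulationConfig, make_eligibility_fixture, simulate_person_periods


@pytest.fixture(scope="session")
def catalog():
    return CodeCatalog()


@pytest.fixture(scope="session")
def fixture_db():
    """Hand-built eligibility fixture: (database, expected decisions, admin end)."""
    return make_eligibility_fixture()


@pytest.fixture(scope="session")
def small_pp():
    """A modest person-period table with confounding, reused across estimation tests."""
    cfg = SimulationConfig(
        n_patients=1500, seed=42, max_intervals=5, baseline_interval_hazard=0.03,
        baseline_prevalence={"diabetes": 0.10, "ra": 0.05, "asthma_copd": 0.10},
    )
    pp, truth = simulate_person_periods(cfg)
    return pp, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
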