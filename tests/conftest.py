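import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_store():
    """A small simulated, deduplicated, annotated case store with ground truth."""
    from pvsignals.synthetic_data import SimulationConfig, simulate_database
    from pvsignals.vocabulary import annotate_store

    cfg = SimulationConfig(n_cases=2000, duplicate_rate=0.1, seed=7)
    store, truth = simulate_database(cfg)
    annotate_store(store)
    return cfg, store, truth
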