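import pytest

from movscreen.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (62 cases, 9 controls, planted variant)."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """Minimal config for replicate loops: only the planted variant."""
    return SimulationConfig(n_variants=1, seed=0)
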