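import pytest

from synanchor.simulate import (
    SimulationConfig,
    run_anchoring,
    simulate_anchoring_scenario,
)


@pytest.fixture(scope="session")
def clean_scenario():
    """A rearrangement-free, noise-free anchoring scenario (fixed seed)."""
    cfg = SimulationConfig(
        seed=42, translocation_rate=0.0, inversion_rate=0.0, false_hit_rate=0.0
    )
    return simulate_anchoring_scenario(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_scenario):
    return run_anchoring(clean_scenario)
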