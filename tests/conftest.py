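import numpy as np
import pytest

from perclos import (
    DEFAULT_STATE,
    PerclosSeries,
    StateModel,
    SyntheticSpec,
    generate_feature_sessions,
    simulate_states,
)


@pytest.fixture(scope="session")
def table_state() -> StateModel:
    """The reference state-transition parameters used as generating truth."""
    return DEFAULT_STATE


@pytest.fixture(scope="session")
def mid_range_series() -> PerclosSeries:
    """A trajectory that stays well away from the 0/1 bounds."""
    rng = np.random.default_rng(7)
    vals = 0.5 + 0.25 * np.sin(np.linspace(0, 9, 200)) + rng.normal(0, 0.02, 200)
    return PerclosSeries(np.clip(vals, 0.05, 0.95))


@pytest.fixture(scope="session")
def small_sessions():
    """Three short feature-level synthetic sessions with ground truth."""
    spec = SyntheticSpec(n_sessions=3, steps_per_session=40, seed=5)
    return spec, generate_feature_sessions(spec)


@pytest.fixture(scope="session")
def long_trajectory(table_state) -> PerclosSeries:
    return simulate_states(table_state, 2000, x0=0.2, seed=42)
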