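import numpy as np
import pytest

from edupulse import (
    DotPlotSummary,
    SimConfig,
    apply_hypotheses,
    default_study_protocol,
    endpoint_summary,
    simulate,
    steady_state,
)


@pytest.fixture(scope="session")
def protocol():
    return default_study_protocol()


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def forward_triplet(protocol, sim_config):
    """Noise-free dot-plot triplet for hypothesis-mode (a_G, a_M)."""

    def _make(a_G: float, a_M: float) -> DotPlotSummary:
        rates, labeling = apply_hypotheses(a_G, a_M)
        initial = steady_state(rates).initial_state()
        return endpoint_summary(simulate(rates, labeling, protocol, initial, sim_config))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
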