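import numpy as np
import pytest

from shipquant.gating import apply_gates
from shipquant.panel import default_gate_config, default_populations, tfr_demo_receptor
from shipquant.simulate import AssayDesign, simulate_cytometry


@pytest.fixture(scope="session")
def mixed_events():
    """Small mixed-population TfR-like simulation shared across tests."""
    design = AssayDesign(
        timepoints=(30.0, 240.0), n_events=2000, n_tech=2, n_donors=1, seed=11
    )
    return simulate_cytometry(design, default_populations(), [tfr_demo_receptor()])


@pytest.fixture(scope="session")
def gated_events(mixed_events):
    return apply_gates(mixed_events, default_gate_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
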