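import numpy as np
import pytest

from affinichrom import ColumnSystem, default_truth, published


@pytest.fixture
def ra_truth():
    """Rosmarinic-acid-like ground truth at the study's column settings."""
    return default_truth(seed=0)


@pytest.fixture
def ra_concentrations():
    """RA concentration grid in mol/L (0.3-1.1 mM, 9 levels)."""
    return [c * 1e-3 for c in published.CONCENTRATION_GRIDS_MM["rosmarinic_acid"]]


@pytest.fixture
def column():
    return ColumnSystem(t0=published.VOID_TIME_MIN, flow_rate=published.BINDING_FLOW_ML_MIN)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
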