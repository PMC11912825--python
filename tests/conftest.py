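import numpy as np
import pytest

from mimicspike.design import default_panel_configs, design_panel

PANEL_SEED = 20250925


@pytest.fixture(scope="session")
def panel9():
    """Default-settings designed panel: GC 40/50/60% x lengths 300/450/600."""
    return design_panel(default_panel_configs(PANEL_SEED))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
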