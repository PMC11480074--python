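import numpy as np
import pytest

from alphamicro import physics
from alphamicro.dataset import DesignPoint, build_dataset, build_design_table


@pytest.fixture(scope="session")
def model():
    return physics.RangeEnergyModel()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully-schemed dataset spanning all 8 source regions.

    60 designs x 2000 hits: enough for surrogate smoke/overfit tests while
    keeping the suite fast.
    """
    rng = np.random.default_rng(np.random.SeedSequence(7).spawn(1)[0])
    designs = build_design_table(rng)
    idx = np.unique(np.linspace(0, len(designs) - 1, 60).round().astype(int))
    return build_dataset([designs[i] for i in idx], 2000, seed=7)


@pytest.fixture
def nucleus_design():
    return DesignPoint(1, 5.867, 5.0, 10.0)
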