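import numpy as np
import pytest

import berryvis as bv


@pytest.fixture(scope="session")
def default_spectra() -> bv.SpectraSet:
    """The default four-class population (625 fruit, 121 bands)."""
    return bv.generate_spectra(bv.SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def small_cube() -> bv.Hypercube:
    """A small scene with known truth masks: 5 fruit, glare, defects."""
    layout = bv.SceneLayout(
        n_fruit=5, rows=96, cols=144, defect_fraction=0.25,
        glare_fraction=0.03, classes=(1, 2, 3, 4, 1),
    )
    return bv.generate_hypercube(bv.SimulationConfig(seed=202), layout)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
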