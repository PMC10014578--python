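import numpy as np
import pytest

from ooclust import OocyteScenario, generate_oocyte_series


@pytest.fixture(scope="session")
def small_scenario():
    """A compact live-regime oocyte: fast to render, NEBD mid-series."""
    return OocyteScenario(
        cell_radius=14.0,
        nucleus_radius=9.0,
        n_chromosomes=4,
        chromosome_radius=1.5,
        nebd_time=35.0,
        n_frames=12,
        frame_interval=5.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_series(small_scenario):
    return generate_oocyte_series(small_scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
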