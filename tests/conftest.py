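import numpy as np
import pytest

from prcarbon import forcing, respiration


@pytest.fixture(scope="session")
def small_forcing():
    """Noise-free 6x12 grid, 20 years, trends in every driver."""
    return forcing.make_forcing(
        grid_shape=(6, 12),
        years=(1900, 1919),
        trend_spec={"ca": 1.0, "tair": 0.02, "fapar": 0.001, "vpd": 1.0},
        noise_spec={"sd": 0},
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_forcing():
    return forcing.make_forcing(grid_shape=(6, 12), years=(1900, 1919), seed=12)


@pytest.fixture(scope="session")
def resp_params(small_forcing):
    table = respiration.default_pft_table(int(small_forcing["pft"].values.max()) + 1)
    return respiration.assign_pft_params(small_forcing["pft"], table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
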