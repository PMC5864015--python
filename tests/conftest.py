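import numpy as np
import pytest

from graztox import LandscapeConfig, Pasture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """1.44 ha pasture, enough structure for behavioral tests."""
    return LandscapeConfig(width_cells=120, height_cells=120, seed=11)


@pytest.fixture(scope="session")
def small_pasture(small_config):
    return Pasture.generate(small_config)


def make_flat_pasture(
    size: int = 30,
    forage: float = 50.0,
    msal: float = 0.0,
    water: tuple[int, int] | None = None,
    margin: int = 0,
) -> Pasture:
    """Hand-built uniform pasture for deterministic engine tests."""
    from graztox.landscape import neighborhood_mean

    accessible = np.zeros((size, size), dtype=bool)
    accessible[margin:size - margin or None, margin:size - margin or None] = True
    forage_grid = np.full((size, size), float(forage))
    msal_grid = np.full((size, size), float(msal))
    if water is None:
        water = (size // 2, size // 2)
    return Pasture(
        accessible=accessible,
        forage_g=forage_grid.copy(),
        initial_forage_g=forage_grid.copy(),
        n_forage_g=neighborhood_mean(forage_grid, 3.0),
        msal_mg=msal_grid.copy(),
        initial_msal_mg=msal_grid.copy(),
        times_grazed=np.zeros((size, size), dtype=np.int64),
        water_cells={water},
    )
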