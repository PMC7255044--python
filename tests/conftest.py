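import numpy as np
import pytest

from clusterflim import DecayCube
from clusterflim.synthetic import (
    SceneLayout,
    block_layout,
    fig2_species_panel,
    gaussian_irf,
    simulate_image,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """A tiny Poisson cube with a decaying expectation per channel."""
    lam = 5.0 * np.exp(-np.arange(16) / 4.0) + 0.2
    counts = rng.poisson(lam, size=(6, 7, 16))
    return DecayCube(counts, channel_width=100.0, meta={"excitation_nm": "530"})


@pytest.fixture(scope="session")
def panel5():
    return fig2_species_panel(5)


@pytest.fixture(scope="session")
def panel4():
    return fig2_species_panel(4)


@pytest.fixture(scope="session")
def two_species_image():
    """Small bright two-species image with ground truth (fast to cluster).

    256 channels and 48x48 pixels keep unit tests quick; the decays use
    the instrument defaults otherwise.
    """
    species = fig2_species_panel(5)[::4]  # most-separated pair
    layout = block_layout(2, shape=(48, 48), mean_counts=1000.0)
    irf = gaussian_irf(256, 19.97, t0=300.0, fwhm=100.0)
    cube, truth = simulate_image(
        species, layout, irf=irf, dt=19.97, n_channels=256, seed=7
    )
    return cube, truth, species
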