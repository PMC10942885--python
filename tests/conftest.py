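import numpy as np
import pytest

from agbsat.raster import SpectralTable
from agbsat.scene_sim import (
    BiomassDistribution,
    CanopyModelParams,
    TrialDesign,
    sample_trial,
    simulate,
)


@pytest.fixture(scope="session")
def default_design() -> TrialDesign:
    return TrialDesign()


@pytest.fixture(scope="session")
def default_dist() -> BiomassDistribution:
    return BiomassDistribution()


@pytest.fixture(scope="session")
def default_canopy() -> CanopyModelParams:
    return CanopyModelParams()


@pytest.fixture(scope="session")
def default_plots(default_design, default_dist):
    return sample_trial(default_design, default_dist, seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """A small rendered trial shared across tests (24 plots, 12 high)."""
    design = TrialDesign(n_plots=24, n_high_density=12, n_blocks=2)
    return simulate(design, seed=11)


@pytest.fixture()
def band_table(default_plots, default_canopy):
    """Noise-free closed-form band table for the default trial's plots."""
    from agbsat.scene_sim import expected_table

    return expected_table(default_plots, default_canopy)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def high_density_table(scene) -> SpectralTable:
    """Zonal band table restricted to the scene's high-density plots."""
    from agbsat.indices import make_nir3
    from agbsat.raster import attach_agb, zonal_means

    table = attach_agb(zonal_means(scene.raster, scene.features), scene.truth)
    keep = set(scene.truth.loc[scene.truth.high_density, "plot_id"])
    idx = [i for i in table.bands.index if i in keep]
    return make_nir3(SpectralTable(table.bands.loc[idx], table.agb.loc[idx]))
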