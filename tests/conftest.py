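import numpy as np
import pytest

import diadrom as dd


@pytest.fixture(scope="session")
def network20() -> dd.BasinNetwork:
    """Default 20-basin latitudinal chain."""
    return dd.make_network(20, seed=7)


@pytest.fixture(scope="session")
def climate60(network20) -> dd.ClimateSeries:
    """60-year stationary seasonal climate over the default chain."""
    return dd.make_climate(network20, years=60, seed=7)


@pytest.fixture(scope="session")
def species() -> dd.SpeciesParameters:
    return dd.SpeciesParameters()


@pytest.fixture(scope="session")
def result60(network20, climate60, species) -> dd.SimulationResult:
    """One 60-year reference run on the default fixture."""
    return dd.run(network20, climate60, species, dd.SimulationConfig(years=60, seed=3))


def constant_climate(network, temperature: float, years: int = 12) -> dd.ClimateSeries:
    """A climate with the same water temperature everywhere, all seasons."""
    return dd.make_climate(
        network,
        base_temp_at_ref_lat=temperature,
        lapse=0.0,
        seasonal_amplitude=0.0,
        years=years,
        noise_sd=0.0,
        seed=0,
    )


def manual_result(reproduced, recruits=None, latitudes=None,
                  first_age=None) -> dd.SimulationResult:
    """Assemble a SimulationResult directly from per-(year, basin) arrays."""
    reproduced = np.asarray(reproduced, dtype=bool)
    n_years, n = reproduced.shape
    recruits = (
        np.zeros((n_years, n)) if recruits is None else np.asarray(recruits, dtype=float)
    )
    latitudes = (
        np.linspace(40.0, 55.0, n) if latitudes is None else np.asarray(latitudes, float)
    )
    first_age = (
        np.full((n_years, n), np.nan) if first_age is None else np.asarray(first_age, float)
    )
    return dd.SimulationResult(
        basin_ids=[f"b{i:03d}" for i in range(n)],
        latitudes=latitudes,
        years=np.arange(n_years),
        recruits=recruits,
        spawners=np.zeros((n_years, n)),
        reproduced=reproduced,
        first_spawner_age=first_age,
        first_spawner_weight=np.where(np.isnan(first_age), 0.0, 1.0),
        total_weight=np.zeros(n_years),
        ticks=n_years * 4,
        seed=0,
    )
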