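"""Synthetic basin networks, climates and virtual-species distributions.

These generators emulate the statistical structure of the real inputs the
models were designed for — a latitudinal chain of Atlantic-coast river
basins with heterogeneous drainage areas, seasonal water temperatures
declining with latitude, a slow warming trajectory, and a historical
presence/absence map generated from a thermal-suitability rule — so every
other module can be exercised without any external download.

The default fixture (20 basins, 60 years) is sized so that complete test
runs, including a small ABC parameter-recovery experiment, finish in
minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demography import ThermalResponse, thermal_dome
from .environment import SEASONS, Basin, BasinNetwork, ClimateSeries

#: Latitudinal extent of the emulated coastal chain (degrees north).
DEFAULT_LAT_RANGE = (37.0, 59.8)

#: Log-normal drainage-area parameters (log-km^2): median ~8100 km^2 with a
#: heavy right tail, matching the mix of small coastal basins and a few
#: large drainages.
DEFAULT_AREA_LOGNORMAL = (9.0, 1.0)

#: Seasonal offsets (degC) around the annual mean: winter coldest, summer
#: warmest, spring and fall transitional.
SEASON_OFFSETS = {"winter": -1.0, "spring": 0.0, "summer": 1.0, "fall": 0.0}


def make_network(
    n_basins: int = 20,
    lat_range: tuple[float, float] = DEFAULT_LAT_RANGE,
    area_lognormal: tuple[float, float] = DEFAULT_AREA_LOGNORMAL,
    coast_lon: float = -2.0,
    seed: int = 0,
) -> BasinNetwork:
    """A meridian-like coastal chain of basins, evenly spaced in latitude.

    Surface areas are drawn log-normally (``area_lognormal`` gives the mean
    and sd of log area in km^2); inter-basin distances are great-circle
    distances between outlets.
    """
    if n_basins < 1:
        raise ValueError("n_basins must be >= 1")
    rng = np.random.default_rng(seed)
    lats = (
        np.linspace(lat_range[0], lat_range[1], n_basins)
        if n_basins > 1
        else np.array([lat_range[0]])
    )
    areas = np.exp(rng.normal(area_lognormal[0], area_lognormal[1], size=n_basins))
    basins = [
        Basin(
            id=f"b{i:03d}",
            outlet_lon=coast_lon,
            outlet_lat=float(lats[i]),
            surface_area=float(areas[i]),
        )
        for i in range(n_basins)
    ]
    return BasinNetwork(basins=basins)


def make_climate(
    network: BasinNetwork,
    base_temp_at_ref_lat: float = 13.0,
    lapse: float = 0.7,
    seasonal_amplitude: float = 6.0,
    warming_per_century: float = 0.0,
    years: int = 60,
    start_year: int = 1901,
    ref_lat: float = 45.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ClimateSeries:
    """Seasonal water-temperature series with a latitudinal gradient.

    Seasonal mean = base - lapse * (lat - ref_lat) + amplitude * offset
    + linear warming + seeded Gaussian noise, where the seasonal offsets
    put winter at -amplitude, summer at +amplitude and spring/fall at the
    annual mean.  The reference window for the constant-reference regime is
    the first decade of the series.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    lats = network.latitudes
    records = []
    for y in range(years):
        year = start_year + y
        warm = warming_per_century * (y / 100.0)
        for season in SEASONS:
            mean = (
                base_temp_at_ref_lat
                - lapse * (lats - ref_lat)
                + seasonal_amplitude * SEASON_OFFSETS[season]
                + warm
            )
            if noise_sd > 0:
                mean = mean + rng.normal(0.0, noise_sd, size=len(lats))
            for bid, t in zip(network.ids, mean):
                records.append((bid, year, season, float(t)))
    table = pd.DataFrame(records, columns=["basin_id", "year", "season", "temperature_C"])
    return ClimateSeries(table, medium="water")


def make_virtual_distribution(
    network: BasinNetwork,
    climate: ClimateSeries,
    thermal_rule: ThermalResponse = ThermalResponse(10.5, 20.0, 26.0),
    threshold: float = 0.5,
    season: str = "summer",
    false_presence_rate: float = 0.0,
    false_absence_rate: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Virtual-species historical presence flags from a thermal rule.

    A basin is present when the dome response evaluated at its
    reference-window seasonal temperature reaches the threshold; optional
    seeded contamination flips presences/absences at the stated rates.
    Returns a boolean Series indexed by basin id.
    """
    rng = np.random.default_rng(seed)
    temps = np.array([climate.reference_mean(bid, season) for bid in network.ids])
    present = thermal_dome(temps, thermal_rule) >= threshold
    present = np.asarray(present, dtype=bool)
    if false_absence_rate > 0:
        flip = present & (rng.random(len(present)) < false_absence_rate)
        present = present & ~flip
    if false_presence_rate > 0:
        flip = ~present & (rng.random(len(present)) < false_presence_rate)
        present = present | flip
    return pd.Series(present, index=pd.Index(network.ids, name="basin_id"), name="present")


def reference_predictors(network: BasinNetwork, climate: ClimateSeries) -> pd.DataFrame:
    """Default correlative-model predictor pool for a basin network.

    Outlet longitude, reference summer temperature at the outlet, and
    drainage surface area (log-transformed downstream by the fitter) —
    the trio the reference species configuration ships with.
    """
    return pd.DataFrame(
        {
            "outlet_lon": [b.outlet_lon for b in network.basins],
            "summer_temperature": [
                climate.reference_mean(bid, "summer") for bid in network.ids
            ],
            "surface_area_km2": network.surface_areas,
        },
        index=pd.Index(network.ids, name="basin_id"),
    )
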