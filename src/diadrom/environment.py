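"""Basin networks and seasonal temperature forcing.

The physical environment of the simulator is a set of river basins, each
reduced to its outlet coordinates and drainage surface area, together with a
seasonal temperature series per basin.  Seasons are fixed calendar quarters
(winter = JFM, spring = AMJ, summer = JAS, fall = OND), so one seasonal time
step equals 0.25 year.  All temperatures handed to the demographic processes
are water temperatures; air temperatures are converted on load with a fixed
linear offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "fall")

#: Regimes accepted by :func:`temperature_at`.
REGIMES: tuple[str, ...] = ("constant-reference", "observed-series", "scenario-series")

EARTH_RADIUS_KM = 6371.0

#: Fixed air-to-water linear offset (degC): water runs 2 degC colder than air.
AIR_WATER_OFFSET = 2.0


def air_to_water(t_air: float | np.ndarray) -> float | np.ndarray:
    """Convert air temperature (degC) to water temperature (degC).

    A basic linear relationship is assumed in which water temperatures are
    2 degC lower than air temperatures.
    """
    return t_air - AIR_WATER_OFFSET


@dataclass(frozen=True)
class Basin:
    """A river basin reduced to its outlet location and drainage area.

    Parameters
    ----------
    id : str
        Unique identifier within a network.
    outlet_lon, outlet_lat : float
        Outlet coordinates in decimal degrees (WGS84-like; no projection
        logic is applied).
    surface_area : float
        Surface area of the drainage basin in km^2 (symbol ``wa``).
    main_stem_length : float, optional
        Length of the main watercourse in km.
    """

    id: str
    outlet_lon: float
    outlet_lat: float
    surface_area: float
    main_stem_length: float | None = None

    def __post_init__(self) -> None:
        if not self.surface_area > 0:
            raise ValueError(f"basin {self.id!r}: surface_area must be > 0")
        if not -90.0 <= self.outlet_lat <= 90.0:
            raise ValueError(f"basin {self.id!r}: latitude out of [-90, 90]")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km) between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def pairwise_distances(
    basins: Sequence[Basin], matrix: np.ndarray | None = None
) -> np.ndarray:
    """Inter-basin distance matrix in km.

    By default distances are great-circle distances between outlets; an
    explicit (e.g. along-coast) matrix may be supplied instead and is
    validated (square, symmetric, non-negative, zero diagonal).
    """
    n = len(basins)
    if n < 1:
        raise ValueError("need at least one basin")
    if matrix is not None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (n, n):
            raise ValueError(f"distance matrix shape {m.shape} != ({n}, {n})")
        if (m < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        return m
    lons = np.array([b.outlet_lon for b in basins])
    lats = np.array([b.outlet_lat for b in basins])
    m = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(m, 0.0)
    return 0.5 * (m + m.T)  # symmetrize floating-point wiggle


@dataclass
class BasinNetwork:
    """An ordered collection of basins plus their pairwise distances (km)."""

    basins: list[Basin]
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [b.id for b in self.basins]
        if len(set(ids)) != len(ids):
            raise ValueError("basin ids must be unique within a network")
        if self.distances is None:
            self.distances = pairwise_distances(self.basins)
        else:
            self.distances = pairwise_distances(self.basins, self.distances)

    def __len__(self) -> int:
        return len(self.basins)

    @property
    def ids(self) -> list[str]:
        return [b.id for b in self.basins]

    @property
    def latitudes(self) -> np.ndarray:
        return np.array([b.outlet_lat for b in self.basins])

    @property
    def surface_areas(self) -> np.ndarray:
        return np.array([b.surface_area for b in self.basins])

    def index_of(self, basin_id: str) -> int:
        return self.ids.index(basin_id)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, distances: np.ndarray | None = None
    ) -> "BasinNetwork":
        """Build a network from a basin table.

        Expected columns: ``id, lon, lat, surface_area_km2`` and optionally
        ``main_stem_km``.
        """
        basins = [
            Basin(
                id=str(row["id"]),
                outlet_lon=float(row["lon"]),
                outlet_lat=float(row["lat"]),
                surface_area=float(row["surface_area_km2"]),
                main_stem_length=(
                    float(row["main_stem_km"]) if "main_stem_km" in frame.columns else None
                ),
            )
            for _, row in frame.iterrows()
        ]
        return cls(basins=basins, distances=distances)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": b.id,
                "lon": b.outlet_lon,
                "lat": b.outlet_lat,
                "surface_area_km2": b.surface_area,
            }
            for b in self.basins
        ]
        return pd.DataFrame(rows)


class ClimateSeries:
    """Seasonal mean water temperature per (basin, year, season).

    Holds a long-format table with columns ``basin_id, year, season,
    temperature_C`` (water temperatures).  Air-temperature input is converted
    on construction when ``medium='air'``.  A reference window of years
    (defaulting to the first decade present) defines the constant-reference
    regime used during spin-up: for every season, the mean over the reference
    years is returned regardless of the requested year.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        medium: str = "water",
        reference_years: tuple[int, int] | None = None,
    ) -> None:
        required = {"basin_id", "year", "season", "temperature_C"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"climate table missing columns: {sorted(missing)}")
        bad = set(table["season"].unique()) - set(SEASONS)
        if bad:
            raise ValueError(f"unknown season labels: {sorted(bad)}")
        if medium not in ("air", "water"):
            raise ValueError("medium must be 'air' or 'water'")
        tab = table.copy()
        tab["basin_id"] = tab["basin_id"].astype(str)
        tab["year"] = tab["year"].astype(int)
        if medium == "air":
            tab["temperature_C"] = air_to_water(tab["temperature_C"].to_numpy(float))
        self.table = tab
        years = np.sort(tab["year"].unique())
        if reference_years is None:
            reference_years = (int(years[0]), int(min(years[0] + 9, years[-1])))
        self.reference_years = reference_years
        self._lookup = {
            (str(b), int(y), s): float(t)
            for b, y, s, t in zip(
                tab["basin_id"], tab["year"], tab["season"], tab["temperature_C"]
            )
        }
        y0, y1 = reference_years
        ref = tab[(tab["year"] >= y0) & (tab["year"] <= y1)]
        self._reference = (
            ref.groupby(["basin_id", "season"])["temperature_C"].mean().to_dict()
        )

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())

    def reference_mean(self, basin_id: str, season: str) -> float:
        key = (str(basin_id), season)
        if key not in self._reference:
            raise KeyError(f"no reference climate for basin {basin_id!r}, {season}")
        return float(self._reference[key])

    def value(self, basin_id: str, year: int, season: str) -> float:
        key = (str(basin_id), int(year), season)
        if key not in self._lookup:
            raise KeyError(f"no climate value for (basin={basin_id!r}, year={year}, season={season})")
        return self._lookup[key]


def temperature_at(
    climate: ClimateSeries,
    basin: Basin | str,
    year: int,
    season: str,
    regime: str = "observed-series",
) -> float:
    """Resolve the water temperature (degC) for one (basin, year, season).

    Under ``constant-reference`` the reference-window seasonal mean is
    returned regardless of ``year``; the series regimes return the stored
    value and raise ``KeyError`` on a missing entry (no silent fallback).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown climate regime {regime!r}; expected one of {REGIMES}")
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    basin_id = basin.id if isinstance(basin, Basin) else str(basin)
    if regime == "constant-reference":
        return climate.reference_mean(basin_id, season)
    return climate.value(basin_id, year, season)
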