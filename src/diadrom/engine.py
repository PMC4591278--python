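"""Seasonal scheduler for the full anadromous life cycle.

The engine advances weighted cohorts ("super-individuals") of identical fish
through a fixed within-season process order:

    survive -> grow (at sea) -> mature -> migrate -> reproduce -> age

Migration is season-gated: in the upstream-migration season mature fish at
sea enter rivers (homing to their natal basin with probability ``p_hom``,
otherwise straying according to the dispersal logit weights with a death
basin); in the reproduction season every basin holding spawners produces
recruits; in the downstream-migration season juveniles old enough (and any
post-spawning survivors) run to sea.  One tick is one calendar season, so a
Y-year run executes exactly 4*Y ticks.

Cohort state is held in parallel numpy arrays so that a century-scale run on
a few dozen basins takes well under a second; by default survival, dispersal
splitting and post-spawning survival act deterministically on cohort weights
(expected-value bookkeeping), while recruitment and growth noise keep the
simulation stochastic.  An optional stochastic dispersal mode draws a single
multinomial destination per straying cohort instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .demography import (
    SEASON_YEARS,
    SpeciesParameters,
    effective_spawners,
    recruitment_capacity,
    river_survival_probability,
    sea_survival_probability,
    thermal_dome,
)
from .dispersal import basin_weight
from .environment import SEASONS, BasinNetwork, ClimateSeries, temperature_at


@dataclass
class SimulationConfig:
    """Run settings for the seasonal scheduler.

    ``spinup_years`` counts the initial years forced with the
    constant-reference climate regime (reference-window seasonal means);
    subsequent years read the stored series.  ``None`` keeps the constant
    regime for the whole run, as in calibration experiments.

    Note that a run starting in any season but winter spills into a final
    partial calendar year; under a series regime the climate must cover that
    year too (a missing entry aborts the run rather than falling back).
    """

    years: int
    initial_juveniles_per_basin: float = 500_000.0
    spinup_years: int | None = None
    seed: int = 0
    replicate_id: int = 0
    start_year: int | None = None
    start_season: str = "summer"
    min_cohort_weight: float = 1e-2
    dispersal_mode: str = "deterministic"  # or "stochastic"
    enable_recruitment: bool = True
    seasons_per_year: int = 4

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.initial_juveniles_per_basin < 0:
            raise ValueError("initial_juveniles_per_basin must be >= 0")
        if self.start_season not in SEASONS:
            raise ValueError(f"unknown start_season {self.start_season!r}")
        if self.dispersal_mode not in ("deterministic", "stochastic"):
            raise ValueError("dispersal_mode must be 'deterministic' or 'stochastic'")
        if self.seasons_per_year != 4:
            raise ValueError("the scheduler is strictly seasonal (4 steps per year)")


@dataclass
class SimulationResult:
    """Per-basin, per-year records of a run.

    ``first_spawner_age`` is the weight-weighted mean age of first-time
    spawners at each reproduction event (NaN when none spawned);
    ``first_spawner_weight`` carries the corresponding total weight so
    means can be re-aggregated across years.
    """

    basin_ids: list[str]
    latitudes: np.ndarray
    years: np.ndarray
    recruits: np.ndarray            # (n_years, n_basins)
    spawners: np.ndarray            # (n_years, n_basins)
    reproduced: np.ndarray          # bool (n_years, n_basins)
    first_spawner_age: np.ndarray   # (n_years, n_basins), NaN when absent
    first_spawner_weight: np.ndarray
    total_weight: np.ndarray        # (n_years,) population size at reproduction
    ticks: int
    seed: int

    @property
    def n_basins(self) -> int:
        return len(self.basin_ids)

    def mean_recruitment(self, window_years: int) -> np.ndarray:
        """Per-basin mean recruit count over the terminal window."""
        self._check_window(window_years)
        return self.recruits[-window_years:].mean(axis=0)

    def mean_first_spawner_age(self, window_years: int | None = None) -> np.ndarray:
        """Per-basin weight-weighted mean age of first-time spawners.

        NaN for basins without any first-time spawner in the window.
        """
        if window_years is None:
            window_years = len(self.years)
        self._check_window(window_years)
        age = self.first_spawner_age[-window_years:]
        w = self.first_spawner_weight[-window_years:]
        num = np.nansum(np.where(np.isnan(age), 0.0, age) * w, axis=0)
        den = np.nansum(np.where(np.isnan(age), 0.0, w), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / den, np.nan)
        return out

    def _check_window(self, window_years: int) -> None:
        if not 1 <= window_years <= len(self.years):
            raise ValueError(
                f"window of {window_years} years exceeds the {len(self.years)}-year record"
            )


def persistence_probability(result: SimulationResult, window_years: int) -> np.ndarray:
    """Per-basin probability of sustaining reproduction.

    The count of years with successful reproduction over the terminal
    window, divided by the window length.
    """
    result._check_window(window_years)
    return result.reproduced[-window_years:].mean(axis=0)


def populated_basins(
    result: SimulationResult,
    recruitment_threshold: float = 50.0,
    window_years: int = 10,
) -> list[str]:
    """Basins whose mean recruitment over the terminal window strictly
    exceeds the threshold (the 50-juvenile rule by default)."""
    mean_rec = result.mean_recruitment(window_years)
    return [bid for bid, m in zip(result.basin_ids, mean_rec) if m > recruitment_threshold]


class _Cohorts:
    """Structure-of-arrays cohort state."""

    __slots__ = ("weight", "age", "length", "natal", "basin", "in_river",
                 "mature", "spawned", "newborn")

    def __init__(self) -> None:
        self.weight = np.empty(0)
        self.age = np.empty(0)
        self.length = np.empty(0)
        self.natal = np.empty(0, dtype=np.int64)
        self.basin = np.empty(0, dtype=np.int64)
        self.in_river = np.empty(0, dtype=bool)
        self.mature = np.empty(0, dtype=bool)
        self.spawned = np.empty(0, dtype=bool)
        self.newborn = np.empty(0, dtype=bool)

    def __len__(self) -> int:
        return self.weight.size

    def keep(self, mask: np.ndarray) -> None:
        for name in self.__slots__:
            setattr(self, name, getattr(self, name)[mask])

    def append(self, **cols) -> None:
        n = len(cols["weight"])
        if n == 0:
            return
        for name in self.__slots__:
            old = getattr(self, name)
            new = np.asarray(cols[name], dtype=old.dtype)
            setattr(self, name, np.concatenate([old, new]))

    def total_weight(self) -> float:
        return float(self.weight.sum())


def _precompute_temperatures(
    network: BasinNetwork,
    climate: ClimateSeries,
    config: SimulationConfig,
    n_year_rows: int,
) -> np.ndarray:
    """Water temperature array of shape (n_year_rows, 4, n_basins)."""
    n = len(network)
    start_year = config.start_year
    if start_year is None:
        start_year = int(climate.years[0])
    spinup = config.spinup_years
    temps = np.empty((n_year_rows, 4, n))
    for y in range(n_year_rows):
        constant = spinup is None or y < spinup
        regime = "constant-reference" if constant else "observed-series"
        year = start_year + y
        for s, season in enumerate(SEASONS):
            for j, b in enumerate(network.basins):
                try:
                    temps[y, s, j] = temperature_at(climate, b, year, season, regime)
                except KeyError as err:
                    raise KeyError(
                        f"missing climate coverage for (basin={b.id!r}, "
                        f"year={year}, season={season})"
                    ) from err
    return temps


def _stray_probability_matrix(
    lengths: np.ndarray,
    natal: np.ndarray,
    distances: np.ndarray,
    areas: np.ndarray,
    p: SpeciesParameters,
) -> np.ndarray:
    """Per-mover destination probabilities over (n_basins + death).

    Row i gives the settlement probabilities for a stray whose natal basin
    is ``natal[i]``; the final column is the death basin.
    """
    d = distances[natal, :]  # (k, n)
    w = basin_weight(d, lengths[:, None], areas[None, :], p)
    total = w.sum(axis=1, keepdims=True) + p.w_death_basin
    probs = np.empty((w.shape[0], w.shape[1] + 1))
    probs[:, :-1] = w / total
    probs[:, -1] = p.w_death_basin / total[:, 0]
    return probs


def run(
    network: BasinNetwork,
    climate: ClimateSeries,
    species: SpeciesParameters,
    config: SimulationConfig,
) -> SimulationResult:
    """Execute the seasonal life-cycle simulation.

    Seeds every basin with juveniles (age ``delta_t_rec``, length ``l_ini``)
    at the first tick, then runs ``config.years * 4`` seasonal ticks,
    recording per-basin, per-year recruitment, spawner counts, reproduction
    success and first-time spawner ages.  Deterministic for a fixed
    (seed, replicate_id) pair.
    """
    p = species
    n = len(network)
    rng = np.random.default_rng([config.seed, config.replicate_id])

    start_idx = SEASONS.index(config.start_season)
    ticks = config.years * 4
    n_year_rows = (start_idx + ticks - 1) // 4 + 1
    temps = _precompute_temperatures(network, climate, config, n_year_rows)

    # per-(year-row, season, basin) survival and growth-dome tables
    s_riv = river_survival_probability(temps, p)
    dome_grow = thermal_dome(temps, p.thermal_grow)
    s_sea = sea_survival_probability(p)
    areas = network.surface_areas
    distances = network.distances
    start_year = config.start_year
    if start_year is None:
        start_year = int(climate.years[0])

    rep_season_idx = SEASONS.index(p.rep_season)
    up_idx = SEASONS.index(p.up_mig_season)
    down_idx = SEASONS.index(p.down_mig_season)

    # per-(year-row, basin) recruitment inputs at the reproduction season
    alpha = recruitment_capacity(p.lambda_rec, areas)
    surv_rep = p.surv_opt_rep * thermal_dome(temps[:, rep_season_idx, :], p.thermal_rep)

    st = _Cohorts()
    if config.initial_juveniles_per_basin > 0:
        st.append(
            weight=np.full(n, float(config.initial_juveniles_per_basin)),
            age=np.full(n, p.delta_t_rec),
            length=np.full(n, p.l_ini),
            natal=np.arange(n),
            basin=np.arange(n),
            in_river=np.ones(n, dtype=bool),
            mature=np.zeros(n, dtype=bool),
            spawned=np.zeros(n, dtype=bool),
            newborn=np.zeros(n, dtype=bool),
        )

    # one record row per reproduction season inside the run
    n_rec_years = config.years
    recruits = np.zeros((n_rec_years, n))
    spawners = np.zeros((n_rec_years, n))
    reproduced = np.zeros((n_rec_years, n), dtype=bool)
    fs_age = np.full((n_rec_years, n), np.nan)
    fs_weight = np.zeros((n_rec_years, n))
    total_w = np.zeros(n_rec_years)
    rec_years = np.empty(n_rec_years, dtype=int)
    rec_row = 0
    min_w = config.min_cohort_weight

    for tick in range(ticks):
        abs_season = start_idx + tick
        season_idx = abs_season % 4
        year_row = abs_season // 4

        # (2) survival
        if len(st):
            riv = st.in_river
            st.weight[riv] *= s_riv[year_row, season_idx, st.basin[riv]]
            st.weight[~riv] *= s_sea
            st.keep(st.weight >= min_w)

        # (3) growth at sea (temperature of the adjacent coastal basin)
        if len(st):
            sea = ~st.in_river
            if sea.any():
                dome = dome_grow[year_row, season_idx, st.basin[sea]]
                kappa = p.k_opt_grow * dome
                dl = (p.l_inf - st.length[sea]) * (1.0 - np.exp(-kappa))
                if p.sigma_dl > 0:
                    eps = rng.normal(0.0, p.sigma_dl, size=int(sea.sum()))
                    dl = dl * np.exp(eps - 0.5 * p.sigma_dl**2)
                st.length[sea] = np.minimum(st.length[sea] + np.maximum(dl, 0.0), p.l_inf)

        # (4) maturation
        if len(st):
            st.mature |= st.length >= p.l_mat

        # (5) season-gated migration / reproduction
        if len(st) and season_idx == up_idx:
            movers = st.mature & ~st.in_river
            if movers.any():
                _upstream_migrate(st, movers, distances, areas, p, rng, min_w, config)

        if season_idx == rep_season_idx:
            rec_years[rec_row] = start_year + year_row
            total_w[rec_row] = st.total_weight()
            if len(st):
                _reproduce(
                    st, n, areas, alpha, surv_rep[year_row], p, rng, config,
                    recruits[rec_row], spawners[rec_row], reproduced[rec_row],
                    fs_age[rec_row], fs_weight[rec_row], min_w,
                )
            rec_row += 1

        if len(st) and season_idx == down_idx:
            down = st.in_river & (st.age >= p.down_mig_age - 1e-9)
            st.in_river[down] = False

        # (6) aging (newborns skip the tick in which they were created)
        if len(st):
            st.age[~st.newborn] += SEASON_YEARS
            st.newborn[:] = False

    return SimulationResult(
        basin_ids=network.ids,
        latitudes=network.latitudes,
        years=rec_years[:rec_row].copy(),
        recruits=recruits[:rec_row],
        spawners=spawners[:rec_row],
        reproduced=reproduced[:rec_row],
        first_spawner_age=fs_age[:rec_row],
        first_spawner_weight=fs_weight[:rec_row],
        total_weight=total_w[:rec_row],
        ticks=ticks,
        seed=config.seed,
    )


def _upstream_migrate(st, movers, distances, areas, p, rng, min_w, config) -> None:
    """Move mature at-sea cohorts into rivers (homing + straying)."""
    idx = np.flatnonzero(movers)
    k = idx.size
    n = areas.size
    w_mov = st.weight[idx]
    natal = st.natal[idx]

    if config.dispersal_mode == "deterministic" and p.p_hom < 1.0:
        probs = _stray_probability_matrix(st.length[idx], natal, distances, areas, p)
        transfer = (1.0 - p.p_hom) * probs[:, :n]
        transfer[np.arange(k), natal] += p.p_hom
        # Arrivals sharing a destination and spawning history are merged into
        # one cohort with weight-conserving mean age and length: settlers are
        # all mature and about to spawn, so within-basin heterogeneity in age
        # and length no longer affects any downstream rate, and merging keeps
        # the cohort count O(n_basins) instead of O(movers x basins).
        ages = st.age[idx]
        lengths = st.length[idx]
        spawned_mov = st.spawned[idx]
        cols = {key: [] for key in ("weight", "age", "length", "basin", "spawned")}
        for flag in (False, True):
            g = spawned_mov == flag
            if not g.any():
                continue
            wg = w_mov[g]
            m = transfer[g]
            w_dest = wg @ m                       # (n,)
            a_dest = (wg * ages[g]) @ m
            l_dest = (wg * lengths[g]) @ m
            jj = np.flatnonzero(w_dest >= min_w)
            cols["weight"].append(w_dest[jj])
            cols["age"].append(a_dest[jj] / w_dest[jj])
            cols["length"].append(l_dest[jj] / w_dest[jj])
            cols["basin"].append(jj)
            cols["spawned"].append(np.full(jj.size, flag))
        st.keep(~movers)
        if cols["weight"]:
            basin = np.concatenate(cols["basin"]).astype(np.int64)
            st.append(
                weight=np.concatenate(cols["weight"]),
                age=np.concatenate(cols["age"]),
                length=np.concatenate(cols["length"]),
                natal=basin,        # settlement imprints future homing
                basin=basin,
                in_river=np.ones(basin.size, dtype=bool),
                mature=np.ones(basin.size, dtype=bool),
                spawned=np.concatenate(cols["spawned"]).astype(bool),
                newborn=np.zeros(basin.size, dtype=bool),
            )
    else:
        # homing-only shortcut, or stochastic single-draw dispersal
        if p.p_hom >= 1.0:
            st.basin[idx] = natal
            st.in_river[idx] = True
            return
        dest = np.empty(k, dtype=np.int64)
        probs = _stray_probability_matrix(st.length[idx], natal, distances, areas, p)
        for i in range(k):
            if rng.random() < p.p_hom:
                dest[i] = natal[i]
            else:
                d = rng.choice(n + 1, p=probs[i])
                dest[i] = -1 if d == n else d  # -1: death basin
        dead = dest < 0
        st.weight[idx[dead]] = 0.0
        alive = idx[~dead]
        st.basin[alive] = dest[~dead]
        st.natal[alive] = dest[~dead]
        st.in_river[alive] = True
        st.keep(st.weight >= min_w)


def _reproduce(st, n, areas, alpha, surv_rep_row, p, rng, config, recruits_row,
               spawners_row, reproduced_row, fs_age_row, fs_weight_row, min_w) -> None:
    """Reproduction in every basin holding spawners, then post-spawning
    survival (weights scaled by ``sp_sp``; survivors flagged and imprinted
    on the basin where they spawned).

    Implements the same Beverton-Holt/Allee/log-normal kernel as
    :func:`diadrom.demography.recruitment`, vectorized over basins with the
    thermal egg-survival term precomputed per year.
    """
    sp_mask = st.in_river & st.mature
    if sp_mask.any():
        s_by_basin = np.bincount(st.basin[sp_mask], weights=st.weight[sp_mask], minlength=n)
        first = sp_mask & ~st.spawned
        fw = np.bincount(st.basin[first], weights=st.weight[first], minlength=n)
        fa = np.bincount(
            st.basin[first], weights=st.weight[first] * st.age[first], minlength=n
        )
    else:
        s_by_basin = np.zeros(n)
        fw = np.zeros(n)
        fa = np.zeros(n)

    spawners_row[:] = s_by_basin
    with np.errstate(invalid="ignore"):
        fs_age_row[:] = np.where(fw > 0, fa / np.maximum(fw, 1e-300), np.nan)
    fs_weight_row[:] = fw

    jj = np.flatnonzero((s_by_basin > 0) & (surv_rep_row > 0)) \
        if config.enable_recruitment else np.empty(0, dtype=int)
    if jj.size:
        s_eff = effective_spawners(s_by_basin[jj], areas[jj], p.eta, p.theta)
        beta = alpha[jj] / (p.fecundity * surv_rep_row[jj])
        r = alpha[jj] * s_eff / (beta + s_eff)
        if p.sigma_rep > 0:
            eps = rng.normal(0.0, p.sigma_rep, size=jj.size)
            r = r * np.exp(eps - 0.5 * p.sigma_rep**2)
        recruits_row[jj] = r
        reproduced_row[jj] = r >= 1.0

    # post-spawning survival and site imprinting
    if sp_mask.any():
        st.weight[sp_mask] *= p.sp_sp
        st.natal[sp_mask] = st.basin[sp_mask]
        st.spawned[sp_mask] = True
        st.keep(st.weight >= min_w)

    if jj.size:
        born = jj[recruits_row[jj] >= min_w]
        if born.size:
            st.append(
                weight=recruits_row[born],
                age=np.full(born.size, p.delta_t_rec),
                length=np.full(born.size, p.l_ini),
                natal=born.astype(np.int64),
                basin=born.astype(np.int64),
                in_river=np.ones(born.size, dtype=bool),
                mature=np.zeros(born.size, dtype=bool),
                spawned=np.zeros(born.size, dtype=bool),
                newborn=np.ones(born.size, dtype=bool),
            )
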