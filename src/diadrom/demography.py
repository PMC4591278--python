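"""Vital rates of the anadromous life cycle.

Every temperature-dependent process uses the same dome-shaped response: a
rational function of water temperature that is 0 at and beyond both thermal
bounds and exactly 1 at the optimum.  Recruitment follows a Beverton-Holt
stock-recruitment relationship modified in two ways: a logistic Allee term
reduces the number of spawners effectively reproducing at low density, and
egg-to-recruit survival (hence the low-density slope of the curve) is
temperature dependent.  Growth at sea is seasonal Von Bertalanffy with the
rate coefficient scaled by the thermal dome.

Units: temperatures degC (water), lengths cm, ages years (0.25 increments),
areas km^2, mortality coefficients per year, one time step = one season.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

SEASON_YEARS = 0.25  # length of one seasonal step, years

#: Unit factor linking the recruitment-capacity coefficient (per m^2) to
#: basin surface areas expressed in km^2.
_KM2_TO_M2 = 1.0e6


@dataclass(frozen=True)
class ThermalResponse:
    """Thermal triplet (t_min < t_opt < t_max, degC) of a dome response."""

    t_min: float
    t_opt: float
    t_max: float

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError(
                f"require t_min < t_opt < t_max, got ({self.t_min}, {self.t_opt}, {self.t_max})"
            )


def thermal_dome(t, resp: ThermalResponse):
    """Dome-shaped thermal performance in [0, 1].

    ``(t - t_min)(t - t_max) / [(t - t_min)(t - t_max) - (t - t_opt)^2]``
    inside the thermal window, 0 at or beyond the bounds, 1 at the optimum.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    num = (t - resp.t_min) * (t - resp.t_max)
    den = num - (t - resp.t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(den != 0.0, num / den, 1.0)
    val = np.where((t <= resp.t_min) | (t >= resp.t_max), 0.0, val)
    return float(val) if val.ndim == 0 else val


# --- species parameters ------------------------------------------------------

#: The 11 uncertain parameters explored in the sensitivity analysis, with
#: their (min, max) ranges.  Thermal lower bounds vary with the rest of the
#: triplet held fixed.
UNCERTAIN_RANGES: dict[str, tuple[float, float]] = {
    "theta": (1.8, 2.2),
    "surv_opt_rep": (5.0e-4, 1.0e-3),
    "tmin_rep": (9.0, 12.0),
    "lambda_rec": (3.0e-4, 5.0e-4),
    "topt_grow": (15.0, 19.0),
    "k_opt_grow": (0.2, 0.5),
    "z_sea": (0.2, 0.6),
    "tmin_surv_riv": (8.0, 11.0),
    "l_mat": (36.0, 44.0),
    "p_hom": (0.6, 0.9),
    "w_death_basin": (0.2, 0.6),
}


@dataclass(frozen=True)
class SpeciesParameters:
    """Full life-history parameter set of the simulated species.

    Defaults are the nominal allis-shad-like values; parameters with an
    uncertainty range default to the centre of that range.
    """

    # reproduction
    rep_season: str = "spring"
    delta_t_rec: float = 0.33        # age (yr) of juveniles at recruitment
    eta: float = 2.4                 # spawners/km^2 anchoring S95
    theta: float = 2.0               # S95/S50 ratio (>1)
    fecundity: float = 135_000.0     # eggs per spawner
    surv_opt_rep: float = 7.5e-4     # optimal egg-to-recruit survival
    thermal_rep: ThermalResponse = field(
        default_factory=lambda: ThermalResponse(10.5, 20.0, 26.0)
    )
    lambda_rec: float = 4.0e-4       # recruitment capacity per m^2 of basin
    sigma_rep: float = 0.2           # log-scale sd of recruitment noise
    sp_sp: float = 0.1               # post-spawning survival probability
    # downstream migration
    down_mig_age: float = 0.33
    down_mig_season: str = "summer"
    # growth
    l_ini: float = 2.0               # juvenile length (cm) in estuary
    sigma_dl: float = 0.2            # log-scale sd of growth-increment noise
    l_inf: float = 60.0              # asymptotic length (cm)
    thermal_grow: ThermalResponse = field(
        default_factory=lambda: ThermalResponse(3.0, 17.0, 26.0)
    )
    k_opt_grow: float = 0.35         # per-season VB rate at the thermal optimum
    # survival
    z_sea: float = 0.4               # annual mortality coefficient at sea
    h_riv: float = 0.0               # annual non-natural mortality in river
    thermal_surv_riv: ThermalResponse = field(
        default_factory=lambda: ThermalResponse(9.5, 20.0, 30.0)
    )
    surv_opt_riv: float = 1.0        # annual optimal natural survival in river
    # maturation
    l_mat: float = 40.0              # length (cm) at first maturity
    # upstream migration / dispersal
    up_mig_season: str = "spring"
    p_hom: float = 0.75              # homing probability
    alpha_const: float = -2.9
    alpha_dist: float = 19.7
    alpha_tl: float = 0.0
    alpha_wa: float = 0.0
    dist_mean: float = 300.0         # km, standardization of dispersal distance
    dist_sd: float = 978.0
    tl_mean: float | None = None     # cm; required only when alpha_tl != 0
    tl_sd: float | None = None
    wa_mean: float | None = None     # km^2; required only when alpha_wa != 0
    wa_sd: float | None = None
    w_death_basin: float = 0.4       # weight of the virtual death basin

    def __post_init__(self) -> None:
        for name in ("surv_opt_rep", "sp_sp", "surv_opt_riv", "p_hom"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.theta <= 1:
            raise ValueError("theta must be > 1")
        if self.fecundity < 0:
            raise ValueError("fecundity must be >= 0")
        if self.l_inf <= self.l_ini:
            raise ValueError("l_inf must exceed l_ini")
        if self.sigma_rep < 0 or self.sigma_dl < 0:
            raise ValueError("log-normal sds must be >= 0")
        if self.w_death_basin < 0:
            raise ValueError("w_death_basin must be >= 0")
        if self.alpha_tl != 0.0 and (self.tl_mean is None or self.tl_sd is None):
            raise ValueError("alpha_tl != 0 requires tl_mean and tl_sd")
        if self.alpha_wa != 0.0 and (self.wa_mean is None or self.wa_sd is None):
            raise ValueError("alpha_wa != 0 requires wa_mean and wa_sd")

    def with_values(self, **updates) -> "SpeciesParameters":
        """Return a copy with named parameters replaced.

        The thermal lower bounds of the uncertain triplets may be set
        directly via ``tmin_rep``, ``topt_grow`` and ``tmin_surv_riv``.
        """
        out = dict(updates)
        if "tmin_rep" in out:
            out["thermal_rep"] = replace(self.thermal_rep, t_min=out.pop("tmin_rep"))
        if "topt_grow" in out:
            out["thermal_grow"] = replace(self.thermal_grow, t_opt=out.pop("topt_grow"))
        if "tmin_surv_riv" in out:
            out["thermal_surv_riv"] = replace(
                self.thermal_surv_riv, t_min=out.pop("tmin_surv_riv")
            )
        return replace(self, **out)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "SpeciesParameters":
        """Build from a flat mapping, rejecting unknown keys.

        Thermal triplets may be given as 3-element lists under
        ``thermal_rep``/``thermal_grow``/``thermal_surv_riv``.
        """
        known = {f.name for f in fields(cls)}
        data: dict[str, object] = {}
        for key, val in mapping.items():
            if key not in known:
                raise KeyError(f"unknown species parameter {key!r}")
            if key.startswith("thermal_") and not isinstance(val, ThermalResponse):
                val = ThermalResponse(*val)  # type: ignore[misc]
            data[key] = val
        return cls(**data)


@dataclass
class SuperIndividual:
    """A weighted cohort of identical fish (scalar view of the engine state)."""

    weight: float
    age: float
    length: float
    natal_basin: str
    location: str          # basin id, "sea:<basin id>", or "dead"
    mature: bool = False
    spawned_before: bool = False

    def __post_init__(self) -> None:
        if self.weight < 0 or self.age < 0:
            raise ValueError("weight and age must be >= 0")


# --- vital-rate operations ---------------------------------------------------

def allee_multiplier(s, wa: float, eta: float, theta: float):
    """Logistic fraction of spawners effectively reproducing.

    Anchored so the fraction is 0.95 at S95 = eta*wa and 0.5 at
    S50 = eta*wa/theta (the ln(19) construction).  Strictly increasing in
    the spawner count ``s`` and always in (0, 1).
    """
    from scipy.special import expit

    s = np.asarray(s, dtype=float)
    s95 = eta * wa
    s50 = eta * wa / theta
    out = expit(np.log(19.0) * (s - s50) / (s95 - s50))
    return float(out) if out.ndim == 0 else out


def effective_spawners(s, wa: float, eta: float, theta: float):
    """Spawner count discounted by the Allee (depensation) term."""
    return s * allee_multiplier(s, wa, eta, theta)


def recruitment_capacity(lambda_rec: float, wa: float) -> float:
    """Asymptotic recruitment of a basin (individuals).

    Reconstruction of the basin-specific Beverton-Holt asymptote: capacity
    scales linearly with drainage surface area, with ``lambda_rec``
    interpreted as a maximum recruit density per m^2 (areas are carried in
    km^2 throughout).  Isolated here so an alternative parameterization can
    be swapped in.
    """
    return lambda_rec * wa * _KM2_TO_M2


def egg_to_recruit_survival(t_water: float, p: SpeciesParameters) -> float:
    """Temperature-dependent survival from eggs to the recruitment age."""
    return p.surv_opt_rep * thermal_dome(t_water, p.thermal_rep)


def recruitment_deterministic(
    s: float, wa: float, t_water: float, p: SpeciesParameters
) -> float:
    """Expected recruit count for ``s`` spawners in a basin of area ``wa``.

    Beverton-Holt with Allee-discounted spawners; the asymptote is the basin
    capacity and the slope at the origin equals fecundity times the
    temperature-dependent egg-to-recruit survival.  Zero when there are no
    spawners or when survival is zero.
    """
    if s <= 0:
        return 0.0
    surv = egg_to_recruit_survival(t_water, p)
    if surv <= 0:
        return 0.0
    alpha = recruitment_capacity(p.lambda_rec, wa)
    beta = alpha / (p.fecundity * surv)
    s_eff = effective_spawners(s, wa, p.eta, p.theta)
    return alpha * s_eff / (beta + s_eff)


def recruitment(
    s: float,
    wa: float,
    t_water: float,
    p: SpeciesParameters,
    rng: np.random.Generator | None = None,
) -> float:
    """Realized recruit count: log-normal noise around the expected kernel.

    The noise is mean-corrected (``-sigma^2/2`` on the log scale) so the
    expectation equals the deterministic kernel.  Exactly zero when there
    are no spawners or thermal survival is zero.
    """
    r_det = recruitment_deterministic(s, wa, t_water, p)
    if r_det == 0.0 or p.sigma_rep == 0.0:
        return r_det
    if rng is None:
        raise ValueError("rng required when sigma_rep > 0")
    eps = rng.normal(0.0, p.sigma_rep)
    return r_det * np.exp(eps - 0.5 * p.sigma_rep**2)


def growth_increment(
    length, t_water, p: SpeciesParameters, rng: np.random.Generator | None = None
):
    """Seasonal Von Bertalanffy length increment (cm) at sea.

    The per-season rate at the thermal optimum is scaled by the growth dome;
    multiplicative unit-mean log-normal noise applies when ``sigma_dl > 0``.
    The result never lets length decrease or exceed the asymptote.
    """
    length = np.asarray(length, dtype=float)
    kappa = p.k_opt_grow * thermal_dome(t_water, p.thermal_grow)
    dl = (p.l_inf - length) * (1.0 - np.exp(-kappa))
    if p.sigma_dl > 0.0:
        if rng is None:
            raise ValueError("rng required when sigma_dl > 0")
        eps = rng.normal(0.0, p.sigma_dl, size=length.shape if length.ndim else None)
        dl = dl * np.exp(eps - 0.5 * p.sigma_dl**2)
    dl = np.clip(dl, 0.0, p.l_inf - length)
    return float(dl) if dl.ndim == 0 else dl


def grow(
    ind: SuperIndividual,
    t_water: float,
    p: SpeciesParameters,
    rng: np.random.Generator | None = None,
) -> float:
    """Apply one seasonal growth step to a cohort; returns the new length."""
    ind.length = float(ind.length + growth_increment(ind.length, t_water, p, rng))
    return ind.length


def sea_survival_probability(p: SpeciesParameters) -> float:
    """Per-season survival at sea, exp(-z_sea/4)."""
    return float(np.exp(-p.z_sea * SEASON_YEARS))


def river_survival_probability(t_water, p: SpeciesParameters):
    """Per-season survival in river.

    Temperature-dependent natural survival (annual optimum ``surv_opt_riv``
    scaled by the thermal dome, taken to the seasonal power) times the
    seasonal decrement of the added mortality coefficient ``h_riv``; zero
    outside the thermal window.
    """
    dome = np.asarray(thermal_dome(t_water, p.thermal_surv_riv))
    base = np.where(dome > 0, np.power(p.surv_opt_riv * np.maximum(dome, 1e-300), SEASON_YEARS), 0.0)
    out = base * np.exp(-p.h_riv * SEASON_YEARS)
    return float(out) if np.ndim(out) == 0 else out


def post_spawning_survival(
    ind: SuperIndividual,
    p: SpeciesParameters,
    rng: np.random.Generator | None = None,
    stochastic: bool = False,
) -> float:
    """Apply post-spawning survival to a cohort's weight.

    In the default deterministic-weight representation the weight is
    multiplied by ``sp_sp``; with ``stochastic=True`` (small populations,
    where demographic noise matters) survivors are a binomial draw over the
    rounded cohort size.  Survivors are flagged as having spawned.
    """
    if stochastic:
        if rng is None:
            raise ValueError("rng required in stochastic mode")
        ind.weight = float(rng.binomial(int(round(ind.weight)), p.sp_sp))
    else:
        ind.weight *= p.sp_sp
    ind.spawned_before = True
    return ind.weight


def is_mature(ind: SuperIndividual, p: SpeciesParameters) -> bool:
    """Maturity check: length at or above the length at first maturity."""
    return ind.length >= p.l_mat
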