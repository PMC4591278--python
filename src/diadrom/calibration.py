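"""Calibration machinery: summary statistics, factorial sensitivity
analysis, and approximate Bayesian computation.

Three scalar summary statistics describe a simulated distribution:

* ``ss1`` — a Bernoulli log-likelihood comparing per-basin persistence
  probabilities with an observed presence/absence map (a small constant
  ``delta`` guards the log at the boundaries); its maximum over probability
  vectors is reached at 1 on presences and 0 on absences.
* ``ss2`` — the latitude of the northernmost populated basin, where
  "populated" means a terminal-window mean recruitment strictly above a
  threshold (50 juveniles by default); undefined (NaN) when no basin
  qualifies.
* ``ss3`` — the sum of squared deviations of per-basin mean first-time
  spawner ages from a target age (5 years).

The sensitivity analysis is a complete two-level factorial design over the
uncertain parameters with replicate runs; indices are factorial-ANOVA
sum-of-squares shares of the total response variance.  The optimization step
is rejection ABC over two parameters, collapsing the three summary
statistics into one scalar discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

SPAWNER_AGE_TARGET = 5.0  # years; observed mean age of first-time spawners
SS1_DELTA = 1e-3


@dataclass(frozen=True)
class SummaryStatistics:
    """The three calibration summary statistics of one simulation."""

    ss1: float
    ss2: float  # NaN when no basin is populated
    ss3: float


def ss1(
    p_sust: Sequence[float],
    observed: Sequence[bool],
    delta: float = SS1_DELTA,
) -> float:
    """Log-likelihood of the observed presence/absence map.

    ``sum(log(p + delta))`` over presences plus ``sum(log(1 - p + delta))``
    over absences, natural log.
    """
    p = np.asarray(p_sust, dtype=float)
    obs = np.asarray(observed, dtype=bool)
    if p.shape != obs.shape:
        raise ValueError("p_sust and observed must cover the same basins")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p_sust values must lie in [0, 1]")
    return float(np.log(p[obs] + delta).sum() + np.log(1.0 - p[~obs] + delta).sum())


def ss2(
    result,
    threshold: float = 50.0,
    window_years: int = 10,
) -> float:
    """Latitude of the northernmost populated basin, NaN when none qualify."""
    from .engine import populated_basins

    pops = populated_basins(result, recruitment_threshold=threshold, window_years=window_years)
    if not pops:
        return float("nan")
    lat = {bid: la for bid, la in zip(result.basin_ids, result.latitudes)}
    return float(max(lat[b] for b in pops))


def ss3(mean_first_spawner_ages: Sequence[float], target: float = SPAWNER_AGE_TARGET) -> float:
    """Sum of squared deviations of mean spawner ages from the target age.

    Only basins that produced at least one first-time spawner contribute
    (NaN entries are skipped).
    """
    ages = np.asarray(mean_first_spawner_ages, dtype=float)
    ages = ages[~np.isnan(ages)]
    return float(((ages - target) ** 2).sum())


def summarize(result, observed: Sequence[bool], window_years: int = 10,
              threshold: float = 50.0) -> SummaryStatistics:
    """Compute all three summary statistics from one simulation result."""
    from .engine import persistence_probability

    p_sust = persistence_probability(result, window_years)
    return SummaryStatistics(
        ss1=ss1(p_sust, observed),
        ss2=ss2(result, threshold, window_years),
        ss3=ss3(result.mean_first_spawner_age(window_years)),
    )


# --- full factorial sensitivity analysis -------------------------------------

@dataclass
class FactorialDesign:
    """Complete two-level design over k parameters with replicate seeds.

    ``matrix`` holds coded levels (-1 for min, +1 for max), one row per
    parameter combination; ``values`` the corresponding physical values.
    """

    names: list[str]
    bounds: dict[str, tuple[float, float]]
    matrix: np.ndarray           # (2^k, k) of +/-1
    replicates: int = 1

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_runs(self) -> int:
        return self.n_rows * self.replicates

    @property
    def values(self) -> pd.DataFrame:
        lo = np.array([self.bounds[n][0] for n in self.names])
        hi = np.array([self.bounds[n][1] for n in self.names])
        vals = lo + (self.matrix + 1.0) / 2.0 * (hi - lo)
        return pd.DataFrame(vals, columns=self.names)


def factorial_design(
    bounds: Mapping[str, tuple[float, float]], replicates: int = 1
) -> FactorialDesign:
    """All 2^k min/max combinations of k parameter ranges."""
    names = list(bounds)
    k = len(names)
    if k < 1:
        raise ValueError("need at least one parameter")
    for name, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"parameter {name!r}: min must be < max")
    rows = 1 << k
    matrix = np.empty((rows, k))
    for j in range(k):
        # column j alternates in blocks of 2^(k-1-j): a balanced, orthogonal design
        block = 1 << (k - 1 - j)
        matrix[:, j] = np.where((np.arange(rows) // block) % 2 == 0, -1.0, 1.0)
    return FactorialDesign(names=names, bounds=dict(bounds), matrix=matrix,
                           replicates=replicates)


@dataclass
class SensitivityIndices:
    """ANOVA variance shares for one response: main effects, pairwise
    interactions, and the residual share (higher-order terms plus replicate
    noise).  All shares lie in [0, 1] and sum to 1."""

    names: list[str]
    main: dict[str, float]
    interaction: dict[tuple[str, str], float]
    residual: float

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.main.items(), key=lambda kv: kv[1], reverse=True)


def sensitivity_indices(
    design: FactorialDesign, responses: np.ndarray
) -> SensitivityIndices:
    """Factorial-ANOVA sensitivity indices from per-run responses.

    ``responses`` has shape (2^k,) or (2^k, replicates); replicate runs
    enter as pure-error degrees of freedom.  The main-effect index of a
    parameter is its contrast sum of squares divided by the total sum of
    squares; pairwise interactions use the product contrast columns.
    Constant responses yield all-zero indices.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != design.n_rows:
        raise ValueError(
            f"expected {design.n_rows} response rows, got {y.shape[0]}"
        )
    r = y.shape[1]
    x = design.matrix
    n_total = y.size
    flat = y.ravel()
    ss_total = float(((flat - flat.mean()) ** 2).sum())
    names = design.names
    k = len(names)
    if ss_total == 0.0:
        return SensitivityIndices(
            names=names,
            main={n: 0.0 for n in names},
            interaction={(names[i], names[j]): 0.0 for i in range(k) for j in range(i + 1, k)},
            residual=0.0,
        )

    def contrast_ss(col: np.ndarray) -> float:
        # replicate each coded entry across the replicate axis
        c = np.repeat(col, r)
        return float(np.dot(c, flat) ** 2 / n_total)

    main = {names[i]: contrast_ss(x[:, i]) / ss_total for i in range(k)}
    interaction = {
        (names[i], names[j]): contrast_ss(x[:, i] * x[:, j]) / ss_total
        for i in range(k)
        for j in range(i + 1, k)
    }
    residual = 1.0 - sum(main.values()) - sum(interaction.values())
    return SensitivityIndices(
        names=names, main=main, interaction=interaction, residual=max(residual, 0.0)
    )


# --- approximate Bayesian computation ----------------------------------------

@dataclass
class ABCResult:
    """Accepted parameter couples and posterior summaries of rejection ABC."""

    names: list[str]
    priors: dict[str, tuple[float, float]]
    accepted: pd.DataFrame          # accepted couples, one column per parameter
    distances: np.ndarray           # discrepancies of accepted draws (sorted)
    all_draws: pd.DataFrame         # every sampled couple with its discrepancy
    acceptance_quantile: float

    def posterior_summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, median, mode (KDE argmax) and credible interval."""
        from scipy.stats import gaussian_kde

        rows = []
        a = (1.0 - level) / 2.0
        for name in self.names:
            v = self.accepted[name].to_numpy()
            lo, hi = np.quantile(v, [a, 1.0 - a])
            if v.std() > 0 and len(v) > 3:
                kde = gaussian_kde(v)
                grid = np.linspace(self.priors[name][0], self.priors[name][1], 512)
                mode = float(grid[np.argmax(kde(grid))])
            else:
                mode = float(np.median(v))
            rows.append(
                {"parameter": name, "mean": v.mean(), "median": float(np.median(v)),
                 "mode": mode, "ci_low": float(lo), "ci_high": float(hi)}
            )
        return pd.DataFrame(rows).set_index("parameter")

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        v = self.accepted[name].to_numpy()
        lo, hi = np.quantile(v, [a, 1.0 - a])
        return float(lo), float(hi)


def abc_discrepancies(
    stats: Sequence[SummaryStatistics],
    ss2_target: float,
    ss3_target: float = 0.0,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Scalar discrepancy per draw from the three summary statistics.

    Components: ``-ss1`` (larger likelihood is better, so smaller is
    better after the sign flip), ``|ss3 - ss3_target|`` (target 0 for the
    observed-age objective) and ``|ss2 - ss2_target|``; each is divided by
    its spread (standard deviation) across the sample before the weighted
    sum.  An undefined ss2 (no populated basin) is treated as the maximal
    ss2 component discrepancy observed in the sample.
    """
    comp = np.column_stack([
        np.array([-s.ss1 for s in stats], dtype=float),
        np.array([abs(s.ss3 - ss3_target) for s in stats], dtype=float),
        np.array([abs(s.ss2 - ss2_target) for s in stats], dtype=float),
    ])
    # undefined ss2 -> maximal component discrepancy
    nan_mask = np.isnan(comp[:, 2])
    if nan_mask.all():
        comp[:, 2] = 0.0
    elif nan_mask.any():
        comp[nan_mask, 2] = np.nanmax(comp[:, 2])
    scaled = np.empty_like(comp)
    for c in range(3):
        spread = comp[:, c].std()
        scaled[:, c] = comp[:, c] / spread if spread > 0 else 0.0
    w = np.asarray(weights, dtype=float)
    return scaled @ w


def abc_calibrate(
    simulator: Callable[[dict[str, float], int], SummaryStatistics],
    priors: Mapping[str, tuple[float, float]],
    ss2_target: float,
    ss3_target: float = 0.0,
    n_draws: int = 2000,
    acceptance_quantile: float = 0.05,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> ABCResult:
    """Rejection ABC over two (or more) parameters.

    ``simulator`` maps (parameter dict, seed) to a
    :class:`SummaryStatistics`.  Couples are sampled uniformly from the
    priors, ranked by the scalar discrepancy, and the configured quantile is
    accepted.
    """
    names = list(priors)
    rng = np.random.default_rng(seed)
    n_accept = int(round(acceptance_quantile * n_draws))
    if n_accept < 1:
        raise ValueError("acceptance quantile too tight: would accept no draws")
    draws = {
        name: rng.uniform(lo, hi, size=n_draws) for name, (lo, hi) in priors.items()
    }
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_draws)
    stats = [
        simulator({n: draws[n][i] for n in names}, int(sim_seeds[i]))
        for i in range(n_draws)
    ]
    d = abc_discrepancies(stats, ss2_target, ss3_target, weights)
    order = np.argsort(d, kind="stable")
    acc = order[:n_accept]
    if acc.size < n_accept:
        raise RuntimeError("fewer acceptances than requested")
    all_draws = pd.DataFrame({n: draws[n] for n in names})
    all_draws["discrepancy"] = d
    all_draws["ss1"] = [s.ss1 for s in stats]
    all_draws["ss2"] = [s.ss2 for s in stats]
    all_draws["ss3"] = [s.ss3 for s in stats]
    accepted = all_draws.iloc[acc].reset_index(drop=True)
    return ABCResult(
        names=names,
        priors=dict(priors),
        accepted=accepted[names],
        distances=d[acc],
        all_draws=all_draws,
        acceptance_quantile=acceptance_quantile,
    )
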