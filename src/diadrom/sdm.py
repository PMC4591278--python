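"""Correlative habitat-suitability model.

A logistic additive model relates per-basin presence/absence to at most
three environmental predictors.  Each predictor enters through a smooth term
with two effective degrees of freedom — realized here as a standardized
quadratic basis (linear + quadratic columns), which spans exactly the
linearly increasing, linearly decreasing and dome-shaped responses the
restriction is meant to allow; the basis is pluggable.  All subsets of one,
two or three candidate predictors are fitted by maximum likelihood and
compared on AIC; the winner is evaluated with Cohen's kappa (at the
kappa-maximizing threshold), rank-based AUC and explained deviance, on both
a calibration split and a held-out validation split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MAX_PREDICTORS = 3
DEFAULT_CALIBRATION_FRACTION = 0.75

#: Predictor columns log-transformed before fitting (heavy-tailed areas).
DEFAULT_LOG_TRANSFORM = ("surface_area_km2",)


def explained_deviance(null_dev: float, final_dev: float) -> float:
    """Percentage of the null-model deviance explained by the fitted model."""
    if null_dev <= 0:
        raise ValueError("null deviance must be > 0")
    if not 0 <= final_dev <= null_dev + 1e-9:
        raise ValueError("final deviance must lie in [0, null deviance]")
    return 100.0 * (null_dev - final_dev) / null_dev


def kappa(observed: Sequence[bool], predicted: Sequence[bool]) -> float:
    """Cohen's kappa from the 2x2 confusion table.

    Observed agreement corrected for the agreement expected by chance from
    the marginal frequencies; NaN when chance agreement is 1 (degenerate
    margins).
    """
    obs = np.asarray(observed, dtype=bool)
    pred = np.asarray(predicted, dtype=bool)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    n = obs.size
    tp = float((obs & pred).sum())
    tn = float((~obs & ~pred).sum())
    p_o = (tp + tn) / n
    p_yes = (obs.sum() / n) * (pred.sum() / n)
    p_no = ((n - obs.sum()) / n) * ((n - pred.sum()) / n)
    p_e = p_yes + p_no
    if np.isclose(p_e, 1.0):
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def auc(observed: Sequence[bool], scores: Sequence[float]) -> float:
    """Rank-based AUC (Mann-Whitney formulation, ties counted half)."""
    from scipy.stats import rankdata

    obs = np.asarray(observed, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(obs.sum())
    n_neg = int((~obs).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[obs].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def best_threshold(observed: Sequence[bool], scores: Sequence[float]) -> float:
    """Kappa-maximizing classification threshold in [0, 1].

    Scans all midpoints between sorted distinct scores plus the end points
    {0, 1}; ties broken toward the smallest threshold.
    """
    obs = np.asarray(observed, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if obs.all() or (~obs).all():
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]])
    best_t, best_k = 0.0, -np.inf
    for t in candidates:
        k = kappa(obs, s >= t)
        if np.isnan(k):
            continue
        if k > best_k + 1e-12:
            best_t, best_k = float(t), k
    return best_t


# --- smooth basis ------------------------------------------------------------

@dataclass(frozen=True)
class QuadraticBasis:
    """Standardized quadratic smooth basis (2 effective df per term)."""

    mean: float
    scale: float

    @classmethod
    def fit(cls, x: np.ndarray) -> "QuadraticBasis":
        scale = float(x.std())
        return cls(mean=float(x.mean()), scale=scale if scale > 0 else 1.0)

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.scale
        return np.column_stack([z, z**2])


@dataclass
class SDMFit:
    """A fitted correlative habitat-suitability model."""

    predictors: list[str]                 # selected predictor names (<= 3)
    bases: dict[str, QuadraticBasis]
    coefficients: np.ndarray              # intercept + 2 per predictor
    log_transform: tuple[str, ...]
    fitted_ranges: dict[str, tuple[float, float]]  # post-transform ranges
    null_deviance: float
    final_deviance: float
    aic: float
    threshold: float                      # kappa-maximizing, from calibration
    calibration_kappa: float
    calibration_auc: float
    validation_kappa: float
    validation_auc: float

    @property
    def explained_deviance(self) -> float:
        return explained_deviance(self.null_deviance, self.final_deviance)

    def linear_predictor(self, predictors: pd.DataFrame) -> np.ndarray:
        x = _apply_log(predictors, self.log_transform)
        cols = [np.ones(len(x))]
        for name in self.predictors:
            cols.append(self.bases[name].transform(x[name].to_numpy()))
        design = np.column_stack(cols)
        return design @ self.coefficients

    def predict(self, predictors: pd.DataFrame) -> np.ndarray:
        """Suitability probabilities (inverse-logit of the additive score)."""
        from scipy.special import expit

        return expit(self.linear_predictor(predictors))

    def response_optimum(self, name: str, grid: np.ndarray) -> float:
        """Argmax of the fitted smooth term for one predictor on a grid.

        The grid is given on the original (pre-log) scale of the predictor.
        """
        if name not in self.predictors:
            raise KeyError(f"{name!r} was not selected by the model")
        g = np.log(grid) if name in self.log_transform else np.asarray(grid, float)
        term = self.bases[name].transform(g) @ self._term_coefs(name)
        return float(np.asarray(grid)[np.argmax(term)])

    def _term_coefs(self, name: str) -> np.ndarray:
        i = self.predictors.index(name)
        return self.coefficients[1 + 2 * i : 3 + 2 * i]


def _apply_log(predictors: pd.DataFrame, log_transform: Sequence[str]) -> pd.DataFrame:
    x = predictors.copy()
    for name in log_transform:
        if name in x.columns:
            if (x[name] <= 0).any():
                raise ValueError(f"cannot log-transform non-positive column {name!r}")
            x[name] = np.log(x[name])
    return x


def _fit_glm(y: np.ndarray, design: np.ndarray):
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=200)


def stratified_split(
    y: np.ndarray, calibration_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of calibration rows, stratified by class."""
    mask = np.zeros(y.size, dtype=bool)
    for cls in (False, True):
        idx = np.flatnonzero(y.astype(bool) == cls)
        n_cal = int(round(calibration_fraction * idx.size))
        chosen = rng.choice(idx, size=n_cal, replace=False)
        mask[chosen] = True
    return mask


def fit_sdm(
    presence_absence: Sequence[bool],
    candidate_predictors: pd.DataFrame,
    calibration_fraction: float = DEFAULT_CALIBRATION_FRACTION,
    seed: int = 0,
    max_predictors: int = MAX_PREDICTORS,
    log_transform: Sequence[str] = DEFAULT_LOG_TRANSFORM,
) -> SDMFit:
    """Exhaustive AIC selection of a <=3-predictor logistic additive model.

    Rows are split into calibration/validation (stratified by class, seeded);
    every subset of one to ``max_predictors`` candidates is fitted on the
    calibration split and the lowest-AIC model wins.  Evaluation metrics are
    computed on both splits; the kappa-maximizing threshold comes from the
    calibration split.  Non-converging candidate subsets are skipped with a
    warning rather than aborting the search.
    """
    y = np.asarray(presence_absence, dtype=float)
    if len(y) != len(candidate_predictors):
        raise ValueError("presence_absence and predictors must align")
    x_all = _apply_log(candidate_predictors, tuple(log_transform))
    rng = np.random.default_rng(seed)
    cal = stratified_split(y, calibration_fraction, rng)
    if y[cal].sum() < 2 or (1 - y[cal]).sum() < 2:
        raise ValueError("calibration split needs >= 2 presences and >= 2 absences")

    names = list(x_all.columns)
    best: tuple[float, list[str], dict, np.ndarray, object] | None = None
    for size in range(1, min(max_predictors, len(names)) + 1):
        for subset in combinations(names, size):
            bases = {
                n: QuadraticBasis.fit(x_all.loc[cal, n].to_numpy()) for n in subset
            }
            design = np.column_stack(
                [np.ones(int(cal.sum()))]
                + [bases[n].transform(x_all.loc[cal, n].to_numpy()) for n in subset]
            )
            try:
                res = _fit_glm(y[cal], design)
                if not np.all(np.isfinite(res.params)):
                    raise ValueError("non-finite coefficients")
            except Exception as err:  # noqa: BLE001 - candidate exclusion, not abort
                logger.warning("candidate subset %s failed to converge: %s", subset, err)
                continue
            if best is None or res.aic < best[0]:
                best = (float(res.aic), list(subset), bases, res.params.copy(), res)
    if best is None:
        raise RuntimeError("no candidate model converged")

    aic_val, subset, bases, params, res = best
    fit = SDMFit(
        predictors=subset,
        bases=bases,
        coefficients=params,
        log_transform=tuple(log_transform),
        fitted_ranges={
            n: (float(x_all.loc[cal, n].min()), float(x_all.loc[cal, n].max()))
            for n in subset
        },
        null_deviance=float(res.null_deviance),
        final_deviance=float(res.deviance),
        aic=aic_val,
        threshold=0.5,
        calibration_kappa=np.nan,
        calibration_auc=np.nan,
        validation_kappa=np.nan,
        validation_auc=np.nan,
    )
    scores_cal = fit.predict(candidate_predictors.loc[cal])
    fit.threshold = best_threshold(y[cal].astype(bool), scores_cal)
    fit.calibration_kappa = kappa(y[cal].astype(bool), scores_cal >= fit.threshold)
    fit.calibration_auc = auc(y[cal].astype(bool), scores_cal)
    val = ~cal
    if y[val].sum() >= 1 and (1 - y[val]).sum() >= 1:
        scores_val = fit.predict(candidate_predictors.loc[val])
        fit.validation_kappa = kappa(y[val].astype(bool), scores_val >= fit.threshold)
        fit.validation_auc = auc(y[val].astype(bool), scores_val)
    return fit


def project_sdm(
    fit: SDMFit, future_predictors: pd.DataFrame
) -> pd.DataFrame:
    """Project the fitted model onto new predictor values.

    Returns a frame with the suitability probability ``p_suit`` per row and
    an ``extrapolated`` flag marking basins whose predictor values fall
    outside the fitted (calibration) range of any selected term.
    """
    if len(future_predictors) == 0:
        return pd.DataFrame({"p_suit": [], "extrapolated": []})
    missing = [n for n in fit.predictors if n not in future_predictors.columns]
    if missing:
        raise KeyError(f"future predictors missing fitted terms: {missing}")
    p = fit.predict(future_predictors)
    x = _apply_log(future_predictors, fit.log_transform)
    extrap = np.zeros(len(x), dtype=bool)
    for name in fit.predictors:
        lo, hi = fit.fitted_ranges[name]
        v = x[name].to_numpy(float)
        extrap |= (v < lo) | (v > hi)
    out = pd.DataFrame({"p_suit": p, "extrapolated": extrap})
    out.index = future_predictors.index
    return out
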