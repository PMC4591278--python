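"""Three-stage dispersal of returning spawners.

Upstream migration is modelled as emigration (homing-vs-straying draw),
transfer (homing fish return to their natal basin; strays weigh every basin
by accessibility and attractiveness through a logit function, with a virtual
"death basin" absorbing failed transfers) and settlement (a multinomial
choice among the weighted destinations).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .demography import SpeciesParameters

DEATH = "death"


def stray_decision(rng: np.random.Generator, p_hom: float) -> str:
    """Single emigration-phase draw: ``"homing"`` with probability p_hom."""
    if not 0.0 <= p_hom <= 1.0:
        raise ValueError("p_hom must be in [0, 1]")
    return "homing" if rng.random() < p_hom else "straying"


def basin_weight(
    distance, fish_length: float, wa, p: SpeciesParameters
):
    """Accessibility-attractiveness weight of a candidate basin, in (0, 1).

    Logistic of a linear score in standardized dispersal distance (entering
    negatively: nearby basins are near-certainly accessible, remote ones are
    not), standardized fish total length and standardized basin surface
    area.  Terms with zero coefficients vanish regardless of their
    standardization constants.
    """
    distance = np.asarray(distance, dtype=float)
    score = p.alpha_const - p.alpha_dist * (distance - p.dist_mean) / p.dist_sd
    if p.alpha_tl != 0.0:
        score = score + p.alpha_tl * (fish_length - p.tl_mean) / p.tl_sd
    if p.alpha_wa != 0.0:
        score = score + p.alpha_wa * (np.asarray(wa, dtype=float) - p.wa_mean) / p.wa_sd
    from scipy.special import expit

    out = expit(np.asarray(score))
    return float(out) if out.ndim == 0 else out


def destination_probabilities(weights: Sequence[float], w_death: float) -> np.ndarray:
    """Normalize candidate weights plus the death-basin weight to sum to 1.

    Returns a vector of length ``len(weights) + 1`` whose last entry is the
    death-basin probability.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w_death < 0:
        raise ValueError("weights must be non-negative")
    total = w.sum() + w_death
    if total <= 0:
        raise ValueError("all destination weights are zero")
    return np.concatenate([w, [w_death]]) / total


def sample_destination(
    probabilities: np.ndarray,
    rng: np.random.Generator,
    basin_ids: Sequence[str] | None = None,
) -> int | str:
    """One multinomial settlement draw.

    The last entry of ``probabilities`` is the death basin.  Returns the
    chosen basin id (or ``"death"``) when ``basin_ids`` is given, otherwise
    the chosen index (the death basin being the final index).
    """
    prob = np.asarray(probabilities, dtype=float)
    if prob.ndim != 1 or prob.min() < 0 or not np.isclose(prob.sum(), 1.0):
        raise ValueError("probabilities must be a 1-d stochastic vector")
    idx = int(rng.choice(len(prob), p=prob / prob.sum()))
    if basin_ids is None:
        return idx
    return DEATH if idx == len(prob) - 1 else str(basin_ids[idx])
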