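"""Joint analysis of correlative and mechanistic projections.

Utilities for comparing the two model families on a common basin set:
probability classes, latitude-ordered comparison tables, range-limit
extraction, and a structured congruence report (trend and range-limit
verdicts under user-set tolerances).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Probability classes, half-open on the left: (lo, hi] -> label; 0 is "null".
PROBABILITY_CLASSES: tuple[tuple[float, float, str], ...] = (
    (0.00, 0.25, "low"),
    (0.25, 0.53, "moderate"),
    (0.53, 0.75, "high"),
    (0.75, 1.00, "very high"),
)


def probability_class(p: float) -> str:
    """Map a probability to its class label.

    0 is "null"; then (0, 0.25] low, (0.25, 0.53] moderate, (0.53, 0.75]
    high and (0.75, 1] very high.  The 0.53 bound is the kappa-maximizing
    threshold of the reference correlative model.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p == 0.0:
        return "null"
    for lo, hi, label in PROBABILITY_CLASSES:
        if lo < p <= hi:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def common_extent(
    correlative_basins: Sequence[str],
    mechanistic_basins: Sequence[str],
    latitudes: Mapping[str, float] | None = None,
) -> list[str]:
    """Intersection of the two basin sets, ordered south to north.

    When latitudes are not provided the order of the mechanistic set is
    preserved.  An empty intersection is an error.
    """
    mech = list(dict.fromkeys(mechanistic_basins))
    corr = set(correlative_basins)
    common = [b for b in mech if b in corr]
    if not common:
        raise ValueError("the two basin sets share no geographic entity")
    if latitudes is not None:
        common.sort(key=lambda b: latitudes[b])
    return common


def comparison_table(
    p_suit: Mapping[str, float],
    p_sust: Mapping[str, float],
    latitudes: Mapping[str, float],
    classes: bool = True,
) -> pd.DataFrame:
    """Per-basin joint table over the common extent, latitude-ordered.

    Columns: both probabilities, optionally both class labels and an
    agreement flag (same class), indexed by basin id from south to north.
    ``.attrs['mean_p_suit']`` / ``.attrs['mean_p_sust']`` carry the
    per-period probability means.
    """
    if not p_suit or not p_sust:
        raise ValueError("both probability sets must be non-empty")
    basins = common_extent(list(p_suit), list(p_sust), latitudes)
    missing = [b for b in basins if b not in latitudes]
    if missing:
        raise ValueError(f"basins missing latitude: {missing}")
    rows = {
        "latitude": [latitudes[b] for b in basins],
        "p_suit": [p_suit[b] for b in basins],
        "p_sust": [p_sust[b] for b in basins],
    }
    table = pd.DataFrame(rows, index=pd.Index(basins, name="basin_id"))
    if classes:
        table["class_suit"] = [probability_class(v) for v in table["p_suit"]]
        table["class_sust"] = [probability_class(v) for v in table["p_sust"]]
        table["agreement"] = table["class_suit"] == table["class_sust"]
    table.attrs["mean_p_suit"] = float(table["p_suit"].mean())
    table.attrs["mean_p_sust"] = float(table["p_sust"].mean())
    return table


def heatmap_long(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy long format of a comparison table for external heat-map plotting."""
    long = table.reset_index().melt(
        id_vars=["basin_id", "latitude"],
        value_vars=["p_suit", "p_sust"],
        var_name="model",
        value_name="probability",
    )
    long["model"] = long["model"].map({"p_suit": "correlative", "p_sust": "mechanistic"})
    long["class"] = [probability_class(v) for v in long["probability"]]
    return long


@dataclass(frozen=True)
class RangeLimits:
    """Southern and northern outlet latitudes of the occupied range."""

    southern: float  # NaN when no basin qualifies
    northern: float


def range_limits(
    values: Mapping[str, float] | Mapping[str, bool],
    latitudes: Mapping[str, float],
    class_threshold: float = 0.5,
) -> RangeLimits:
    """Range limits from per-basin probabilities or populated flags.

    A basin qualifies when its value is at or above the threshold (boolean
    flags qualify when true).  Returns NaN limits when none qualify.
    """
    lats = [
        latitudes[b]
        for b, v in values.items()
        if (bool(v) if isinstance(v, (bool, np.bool_)) else v >= class_threshold)
    ]
    if not lats:
        return RangeLimits(float("nan"), float("nan"))
    return RangeLimits(southern=float(min(lats)), northern=float(max(lats)))


def congruence_report(
    table_past: pd.DataFrame,
    table_future: pd.DataFrame,
    trend_tolerance: float = 0.1,
    limit_tolerance_deg: float = 1.0,
    class_threshold: float = 0.5,
) -> dict:
    """Structured congruence verdicts between the two model families.

    Compares the mean-probability trend (future minus past) of each model
    and the predicted northern/southern range limits, declaring congruence
    within the supplied tolerances.  The tolerances are analysis settings,
    not estimated quantities.
    """
    def trend(key: str) -> float:
        return table_future.attrs[key] - table_past.attrs[key]

    t_suit, t_sust = trend("mean_p_suit"), trend("mean_p_sust")

    def limits(table: pd.DataFrame, col: str) -> RangeLimits:
        vals = dict(zip(table.index, table[col]))
        lats = dict(zip(table.index, table["latitude"]))
        return range_limits(vals, lats, class_threshold)

    lim_suit = limits(table_future, "p_suit")
    lim_sust = limits(table_future, "p_sust")
    north_delta = lim_suit.northern - lim_sust.northern
    south_delta = lim_suit.southern - lim_sust.southern
    return {
        "trend": {
            "correlative": t_suit,
            "mechanistic": t_sust,
            "congruent": bool(abs(t_suit - t_sust) <= trend_tolerance),
        },
        "range_limits": {
            "correlative": {"southern": lim_suit.southern, "northern": lim_suit.northern},
            "mechanistic": {"southern": lim_sust.southern, "northern": lim_sust.northern},
            "northern_delta_deg": north_delta,
            "southern_delta_deg": south_delta,
            "congruent": bool(
                np.isfinite(north_delta)
                and np.isfinite(south_delta)
                and abs(north_delta) <= limit_tolerance_deg
                and abs(south_delta) <= limit_tolerance_deg
            ),
        },
    }
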