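"""Frailty Trait Scale (FTS) scoring.

The FTS summarises seven physiological domains of frailty (energy balance
and nutrition, activity, nervous system, vascular system, weakness,
endurance, slowness) through 12 items.  Each item is scored 0 (best) to 4
(worst) — the 30-s chair-stand test is scored 0 to 5 so that people unable
to stand a single time receive the extra worst point — and, where
appropriate, an item is scored against the quintile distribution of the
reference population.  The total is standardised to 0–100:

    total = (sum of item scores / total possible for the individual) * 100

where the denominator counts only the items the individual actually
completed.  A battery is valid only if at least 75% of the items
(9 of 12) were completed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_IDS",
    "FTSItemSpec",
    "default_item_specs",
    "compute_quintile_cutpoints",
    "cutpoints_from_population",
    "score_item",
    "score_battery",
    "total_score",
    "compute_bmi",
    "MIN_ITEMS_SCORED",
]

#: canonical item identifiers, in the order the instrument lists them
ITEM_IDS: tuple[str, ...] = (
    "bmi",
    "waist",
    "weight_loss",
    "albumin",
    "pase",
    "verbal_fluency",
    "balance",
    "ankle_brachial",
    "grip",
    "knee_extension",
    "chair_stand",
    "gait_time",
)

#: completeness rule: at least 9 of the 12 items must be scored
MIN_ITEMS_SCORED: int = 9


@dataclass(frozen=True)
class FTSItemSpec:
    """Scoring specification for one FTS item.

    Parameters
    ----------
    item_id
        One of :data:`ITEM_IDS`.
    max_score
        4 for every item except the chair-stand test (5).
    higher_is_better
        If True the raw scale is reversed before scoring (e.g. grip
        strength: the top population quintile scores 0).
    scoring_mode
        ``"quintile"`` — cutpoints are population 20/40/60/80th
        percentiles; ``"fixed"`` — cutpoints are explicit rule thresholds
        (weight loss, Romberg balance categories, albumin bands).
    cutpoints
        ``max_bins`` ordered boundaries; for quintile items there are 4.
        May be None until :func:`cutpoints_from_population` fills them in.
    zero_raw_score
        Special-case score assigned when the raw value is exactly 0
        (chair stand: unable to rise once scores 5).
    """

    item_id: str
    max_score: int = 4
    higher_is_better: bool = False
    scoring_mode: str = "quintile"
    cutpoints: tuple[float, ...] | None = None
    zero_raw_score: int | None = None

    def __post_init__(self) -> None:
        if self.max_score not in (4, 5):
            raise ValueError(f"{self.item_id}: max_score must be 4 or 5")
        if self.scoring_mode not in ("quintile", "fixed"):
            raise ValueError(f"{self.item_id}: unknown scoring_mode {self.scoring_mode!r}")
        if self.max_score == 5 and self.zero_raw_score is None:
            raise ValueError(
                f"{self.item_id}: a 0-5 item must define the zero-raw special case"
            )
        if self.cutpoints is not None:
            cp = np.asarray(self.cutpoints, dtype=float)
            # always 4 boundaries -> 5 quantile bins; the chair-stand
            # extra point comes from the zero special case, not a 6th bin
            if cp.ndim != 1 or len(cp) != 4:
                raise ValueError(f"{self.item_id}: expected 4 cutpoints, got {len(cp)}")
            if not np.all(np.diff(cp) > 0):
                raise ValueError(f"{self.item_id}: cutpoints must be strictly increasing")


def default_item_specs() -> dict[str, FTSItemSpec]:
    """Default 12-item specification (cutpoints left for the population).

    Directions follow the instrument: anthropometric burden and slowness
    are higher-is-worse; performance, strength, activity and biochemical
    reserve are higher-is-better.  Weight loss and Romberg balance are
    rule-scored against fixed thresholds rather than population quintiles.
    """
    worse = dict(higher_is_better=False)
    better = dict(higher_is_better=True)
    specs = {
        "bmi": FTSItemSpec("bmi", **worse),
        "waist": FTSItemSpec("waist", **worse),
        # percent unintentional weight loss in the last year, banded
        "weight_loss": FTSItemSpec(
            "weight_loss", scoring_mode="fixed", cutpoints=(1.0, 3.0, 5.0, 10.0), **worse
        ),
        "albumin": FTSItemSpec("albumin", **better),
        "pase": FTSItemSpec("pase", **better),
        "verbal_fluency": FTSItemSpec("verbal_fluency", **better),
        # Romberg performance encoded 0 (unable) .. 4 (full tandem hold)
        "balance": FTSItemSpec(
            "balance", scoring_mode="fixed", cutpoints=(0.5, 1.5, 2.5, 3.5), **better
        ),
        "ankle_brachial": FTSItemSpec("ankle_brachial", **better),
        "grip": FTSItemSpec("grip", **better),
        "knee_extension": FTSItemSpec("knee_extension", **better),
        "chair_stand": FTSItemSpec("chair_stand", max_score=5, zero_raw_score=5, **better),
        "gait_time": FTSItemSpec("gait_time", **worse),
    }
    assert tuple(specs) == ITEM_IDS
    return specs


def compute_quintile_cutpoints(values: Sequence[float], item_id: str = "item") -> tuple[float, ...]:
    """20/40/60/80th percentile boundaries of a population of raw values.

    Linear-interpolation empirical quantiles (numpy's default).  Missing
    values are dropped.  Raises if fewer than 5 distinct values remain —
    a degenerate distribution cannot define quintiles.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 5:
        raise ValueError(f"{item_id}: need at least 5 non-missing values for quintiles")
    if np.unique(arr).size < 5:
        raise ValueError(f"{item_id}: fewer than 5 distinct values, quintiles undefined")
    return tuple(np.percentile(arr, [20, 40, 60, 80]))


def cutpoints_from_population(
    raw: pd.DataFrame, specs: Mapping[str, FTSItemSpec]
) -> dict[str, FTSItemSpec]:
    """Fill quintile cutpoints from a long raw-value table.

    ``raw`` has columns ``participant_id, item_id, raw_value``.  Fixed-rule
    items keep their configured cutpoints.  Chair-stand quintiles are
    computed over the positive values only (zero has its own rule).
    """
    out: dict[str, FTSItemSpec] = {}
    for item_id, spec in specs.items():
        if spec.scoring_mode == "fixed":
            out[item_id] = spec
            continue
        vals = raw.loc[raw["item_id"] == item_id, "raw_value"].to_numpy(dtype=float)
        if spec.zero_raw_score is not None:
            vals = vals[vals != 0]
        out[item_id] = replace(spec, cutpoints=compute_quintile_cutpoints(vals, item_id))
    return out


def score_item(raw_value: float | None, spec: FTSItemSpec) -> int | None:
    """Score a single raw value against an item specification.

    Returns None for a missing raw value (never zero: absence of a
    measurement carries no frailty information).  Boundary values fall in
    the lower bin (right-closed intervals); the reversal for
    higher-is-better items maps the best quintile to 0.
    """
    if raw_value is None or (isinstance(raw_value, float) and np.isnan(raw_value)):
        return None
    if spec.zero_raw_score is not None and raw_value == 0:
        return spec.zero_raw_score
    if spec.cutpoints is None:
        raise ValueError(f"{spec.item_id}: cutpoints not set")
    cp = np.asarray(spec.cutpoints, dtype=float)
    bin_idx = int(np.searchsorted(cp, raw_value, side="left"))  # raw <= cp[k] -> bin k
    n_top = len(cp)
    score = (n_top - bin_idx) if spec.higher_is_better else bin_idx
    return int(score)


def total_score(
    scores: Mapping[str, int | None], specs: Mapping[str, FTSItemSpec]
) -> tuple[float | None, bool, int]:
    """Standardised 0–100 total for one participant.

    Returns ``(total, valid, n_scored)``.  Missing items are excluded from
    both numerator and denominator (the denominator is the total possible
    *for the individual*).  Batteries with fewer than 9 scored items are
    invalid and get a None total.
    """
    num = 0
    den = 0
    n_scored = 0
    for item_id, spec in specs.items():
        s = scores.get(item_id)
        if s is None:
            continue
        if not 0 <= s <= spec.max_score:
            raise ValueError(f"{item_id}: score {s} outside [0, {spec.max_score}]")
        num += s
        den += spec.max_score
        n_scored += 1
    if n_scored < MIN_ITEMS_SCORED:
        return None, False, n_scored
    return 100.0 * num / den, True, n_scored


def score_battery(
    raw: pd.DataFrame,
    specs: Mapping[str, FTSItemSpec] | None = None,
    cutpoints_from_data: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a long battery table for a whole population.

    Parameters
    ----------
    raw
        Columns ``participant_id, item_id, raw_value``; one row per
        observed measurement (missing items simply absent, or NaN).
    specs
        Item specifications; defaults to :func:`default_item_specs`.
    cutpoints_from_data
        If True, quintile cutpoints are computed from this population
        (the instrument's reference-population convention).

    Returns
    -------
    scored, totals
        ``scored``: the long table with an added ``score`` column.
        ``totals``: one row per participant with ``total_score``,
        ``valid``, ``n_scored``.
    """
    if specs is None:
        specs = default_item_specs()
    unknown = set(raw["item_id"]) - set(specs)
    if unknown:
        raise ValueError(f"unknown item ids: {sorted(unknown)}")
    if cutpoints_from_data:
        specs = cutpoints_from_population(raw, specs)

    scored = raw.copy()
    scored["score"] = [
        score_item(v, specs[i]) for v, i in zip(scored["raw_value"], scored["item_id"])
    ]

    rows = []
    for pid, grp in scored.groupby("participant_id", sort=True):
        per_item = dict(zip(grp["item_id"], grp["score"]))
        tot, valid, n_scored = total_score(per_item, specs)
        rows.append(
            {"participant_id": pid, "total_score": tot, "valid": valid, "n_scored": n_scored}
        )
    return scored, pd.DataFrame(rows)


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m**2
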