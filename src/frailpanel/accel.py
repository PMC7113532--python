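"""Reduction of 1-min accelerometer count streams to SB/MVPA summaries.

Hip-worn uniaxial accelerometry collected in 1-minute epochs is reduced to
daily and per-person summaries of sedentary behaviour (SB, <100 counts/min),
moderate-to-vigorous physical activity (MVPA, >=1952 counts/min) and wear
time, under the standard validity rules for older-adult cohorts:

* non-wear: runs of >=60 consecutive minutes of zero counts, tolerating up
  to 2 consecutive interruption minutes with counts above zero but below
  100; any minute at >=100 counts breaks the run (the Troiano-family
  convention);
* a day is valid with >=8 h of wear and no minute above 20,000 counts;
* a participant is valid with >=4 valid days; behaviour minutes are
  averaged over valid days only.

Minutes are 0-based within the day; intervals are half-open [start, end);
days are processed independently (waking-hours protocols do not span
midnight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NonwearConfig",
    "ValidityConfig",
    "DaySummary",
    "ActivitySummary",
    "detect_nonwear",
    "detect_nonwear_day",
    "flag_spikes",
    "summarize_day",
    "summarize_days",
    "summarize_participant",
    "summarize_participants",
    "read_epochs_csv",
]

SB_CUT = 100        # counts/min below which a worn minute is sedentary
MVPA_CUT = 1952     # counts/min at or above which a worn minute is MVPA
SPIKE_CEILING = 20_000  # counts/min above which the whole day is invalid


@dataclass(frozen=True)
class NonwearConfig:
    """Non-wear detection parameters.

    window_min
        Minimum total run length (minutes) to qualify as non-wear.
    allowance_max
        Maximum number of consecutive tolerated interruption minutes
        inside a run; 0 gives the strict zeros-only reading.
    allowance_ceiling
        Interruption minutes must have counts strictly below this value
        (and above zero); counts at or above it always break the run.
    """

    window_min: int = 60
    allowance_max: int = 2
    allowance_ceiling: int = 100

    def __post_init__(self) -> None:
        if self.window_min < 1 or self.allowance_max < 0 or self.allowance_ceiling < 1:
            raise ValueError("invalid non-wear configuration")


@dataclass(frozen=True)
class ValidityConfig:
    """Day- and participant-level validity thresholds."""

    min_wear_min: int = 480       # 8 h of wear per day
    min_valid_days: int = 4
    spike_ceiling: int = SPIKE_CEILING
    sb_cut: int = SB_CUT
    mvpa_cut: int = MVPA_CUT


@dataclass(frozen=True)
class DaySummary:
    participant_id: str
    day: object
    wear_min: int
    sb_min: int
    mvpa_min: int
    light_min: int
    has_spike: bool
    valid: bool


@dataclass(frozen=True)
class ActivitySummary:
    participant_id: str
    n_valid_days: int
    mean_wear_min: float
    mean_sb_min: float
    mean_mvpa_min: float
    valid_participant: bool


def _check_counts(counts: np.ndarray) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        flo = np.asarray(arr, dtype=float)
        if np.any(np.isnan(flo)) or np.any(flo != np.round(flo)):
            raise ValueError("counts must be non-negative integers")
        arr = flo.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64, copy=False)


def detect_nonwear_day(counts: np.ndarray, config: NonwearConfig | None = None) -> np.ndarray:
    """Per-minute wear mask (True = worn) for one day's count vector.

    A non-wear run is a maximal stretch of zero-count minutes in which up
    to ``allowance_max`` consecutive minutes with counts in
    (0, allowance_ceiling) are tolerated (and counted as non-wear); the
    run can neither start nor end on a tolerated interruption minute.
    Runs of total length >= ``window_min`` are non-wear; everything else
    is wear.  An empty day yields an empty mask.
    """
    if config is None:
        config = NonwearConfig()
    counts = _check_counts(counts)
    n = counts.size
    wear = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        if counts[i] != 0:
            i += 1
            continue
        # grow a candidate run starting at a zero minute
        j = i
        end = i  # one past the last zero minute accepted into the run
        while j < n:
            if counts[j] == 0:
                j += 1
                end = j
                continue
            # interruption attempt
            k = j
            while (
                k < n
                and 0 < counts[k] < config.allowance_ceiling
                and k - j < config.allowance_max
            ):
                k += 1
            if k < n and counts[k] == 0:
                j = k  # tolerated; zeros resume
                continue
            break  # breaker minute, over-long interruption, or end of day
        if end - i >= config.window_min:
            wear[i:end] = False
        i = max(j, i + 1)
    return wear


def detect_nonwear(
    epochs: pd.DataFrame, config: NonwearConfig | None = None
) -> pd.Series:
    """Wear mask for an epoch table (columns participant_id, date, minute, counts).

    Days are processed independently; the returned boolean Series is
    aligned with the input index.
    """
    _validate_epochs(epochs)
    mask = pd.Series(True, index=epochs.index, name="worn")
    for _, grp in epochs.groupby(["participant_id", "date"], sort=False):
        grp = grp.sort_values("minute")
        mask.loc[grp.index] = detect_nonwear_day(grp["counts"].to_numpy(), config)
    return mask


def flag_spikes(
    epochs: pd.DataFrame, worn: pd.Series | None = None, ceiling: int = SPIKE_CEILING
) -> pd.Series:
    """Day-level spike flags: True if any worn minute exceeds ``ceiling``.

    Returned as a Series indexed by (participant_id, date).  The
    comparison is strict: a minute at exactly ``ceiling`` counts is kept.
    """
    _validate_epochs(epochs)
    df = epochs[["participant_id", "date", "counts"]].copy()
    df["spike"] = df["counts"] > ceiling
    if worn is not None:
        df["spike"] &= worn.to_numpy()
    return df.groupby(["participant_id", "date"])["spike"].any()


def _validate_epochs(epochs: pd.DataFrame) -> None:
    required = {"participant_id", "date", "minute", "counts"}
    missing = required - set(epochs.columns)
    if missing:
        raise ValueError(f"epoch table missing columns: {sorted(missing)}")
    minute = epochs["minute"].to_numpy()
    if minute.size and (minute.min() < 0 or minute.max() > 1439):
        raise ValueError("minute-of-day must lie in [0, 1439]")
    for (_, _), grp in epochs.groupby(["participant_id", "date"], sort=False):
        m = np.sort(grp["minute"].to_numpy())
        if np.unique(m).size != m.size:
            raise ValueError("duplicate minutes within a day")


def summarize_day(
    participant_id: str,
    day: object,
    counts: np.ndarray,
    worn: np.ndarray,
    has_spike: bool | None = None,
    config: ValidityConfig | None = None,
) -> DaySummary:
    """DaySummary from one day's counts and wear mask.

    SB/light/MVPA partition the worn minutes exactly; validity requires
    >= ``min_wear_min`` of wear and no spike minute.
    """
    if config is None:
        config = ValidityConfig()
    counts = _check_counts(counts)
    worn = np.asarray(worn, dtype=bool)
    if counts.shape != worn.shape:
        raise ValueError("counts and wear mask must align")
    wc = counts[worn]
    wear_min = int(worn.sum())
    sb_min = int((wc < config.sb_cut).sum())
    mvpa_min = int((wc >= config.mvpa_cut).sum())
    light_min = wear_min - sb_min - mvpa_min
    if has_spike is None:
        has_spike = bool((wc > config.spike_ceiling).any())
    valid = wear_min >= config.min_wear_min and not has_spike
    return DaySummary(
        participant_id=participant_id,
        day=day,
        wear_min=wear_min,
        sb_min=sb_min,
        mvpa_min=mvpa_min,
        light_min=light_min,
        has_spike=bool(has_spike),
        valid=valid,
    )


def summarize_days(
    epochs: pd.DataFrame,
    nonwear: NonwearConfig | None = None,
    validity: ValidityConfig | None = None,
) -> pd.DataFrame:
    """Per-day summary table for an epoch table."""
    if validity is None:
        validity = ValidityConfig()
    worn = detect_nonwear(epochs, nonwear)
    rows = []
    for (pid, day), grp in epochs.groupby(["participant_id", "date"], sort=True):
        grp = grp.sort_values("minute")
        s = summarize_day(
            pid, day, grp["counts"].to_numpy(), worn.loc[grp.index].to_numpy(),
            config=validity,
        )
        rows.append(s.__dict__)
    return pd.DataFrame(rows)


def summarize_participant(
    day_summaries: pd.DataFrame, min_valid_days: int = 4
) -> ActivitySummary:
    """ActivitySummary over one participant's day summaries.

    Means are taken over valid days only; with zero valid days the means
    are NaN and the participant is flagged invalid.
    """
    if day_summaries.empty:
        raise ValueError("at least one day summary required")
    pid = day_summaries["participant_id"].iloc[0]
    valid = day_summaries[day_summaries["valid"]]
    n_valid = len(valid)
    if n_valid == 0:
        return ActivitySummary(pid, 0, float("nan"), float("nan"), float("nan"), False)
    return ActivitySummary(
        participant_id=pid,
        n_valid_days=n_valid,
        mean_wear_min=float(valid["wear_min"].mean()),
        mean_sb_min=float(valid["sb_min"].mean()),
        mean_mvpa_min=float(valid["mvpa_min"].mean()),
        valid_participant=n_valid >= min_valid_days,
    )


def summarize_participants(
    day_summaries: pd.DataFrame, min_valid_days: int = 4
) -> pd.DataFrame:
    """Per-person summary table from a per-day summary table."""
    rows = [
        summarize_participant(grp, min_valid_days).__dict__
        for _, grp in day_summaries.groupby("participant_id", sort=True)
    ]
    return pd.DataFrame(rows)


def read_epochs_csv(path) -> pd.DataFrame:
    """Read an epoch CSV with header participant_id,date,minute,counts."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _validate_epochs(df)
    df["counts"] = _check_counts(df["counts"].to_numpy())
    return df
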