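"""Synthetic two-wave cohort data with known ground truth.

Three generators emulate the inputs of the analysis chain so that every
downstream stage can be tested against a recoverable target:

* :func:`generate_panel` — a wide two-wave panel (frailty, one movement
  behaviour, covariates) drawn from the linear structural equations of a
  cross-lagged panel model with user-chosen standardized coefficients,
  plus MCAR or MAR wave-2 attrition;
* :func:`generate_epochs` — 1-min accelerometer count streams with the
  true wear/non-wear segmentation and true SB/MVPA minutes returned
  alongside;
* :func:`generate_fts_battery` — 12-item frailty-scale raw-value tables
  whose population quintiles match supplied cutpoints.

All variables of the panel are generated on a standardized (unit
variance) scale, so the configured coefficients are exact population
standardized betas; an optional affine mapping produces realistic
FTS-point and min/day files (sedentary time 530.18 +/- 84.86, MVPA
20.12 +/- 23.30 min/day, frailty 35.35 +/- 13.94 points at wave 1),
with MVPA left-truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import fts as fts_mod

__all__ = [
    "CovariateEffect",
    "PanelTruth",
    "generate_panel",
    "implied_covariance",
    "EpochProfile",
    "random_epoch_profile",
    "generate_epochs",
    "generate_fts_battery",
    "extreme_battery",
    "NATURAL_SCALES",
]

# wave-1 (mean, sd) and wave-2 mean used by the natural-scale mapping
NATURAL_SCALES = {
    "frailty": {"t1": (35.35, 13.94), "t2": (43.79, 13.86)},
    "sb": {"t1": (530.18, 84.86), "t2": (542.61, 75.91)},
    "mvpa": {"t1": (20.12, 23.30), "t2": (13.21, 18.73)},
}

# cohort-style covariate marginals (age in years; categorical frequencies
# renormalised over the observed cells)
_COV_MARGINALS = {
    "age": {"mean": 76.68, "sd": 3.90, "gap_years": 3.8},
    "sex_female": 0.527,
    "bmi": {"t1": (30.82, 4.62), "t2": (30.33, 4.40), "stability": 0.9},
    "mmse": {"t1": (24.02, 3.73), "t2": (23.32, 3.54), "stability": 0.8},
    "wear": {"t1": (781.36, 83.14), "t2": (777.61, 74.45), "stability": 0.6},
    "education": {"levels": ["none", "primary", "secondary+"],
                  "probs": [0.760, 0.164, 0.076]},
    "income": {"levels": ["low", "medium", "high"], "probs": [0.476, 0.476, 0.048]},
    "marital": {"levels": ["single", "married", "widowed", "divorced"],
                "probs": [0.038, 0.739, 0.217, 0.006]},
}


@dataclass(frozen=True)
class CovariateEffect:
    """Standardized effects of one covariate on the panel variables.

    ``frailty`` and ``behaviour`` are (wave-1, wave-2) pairs: the effect
    of the covariate's standardized score at each wave on that wave's
    frailty/behaviour variable.
    """

    frailty: tuple[float, float] = (0.0, 0.0)
    behaviour: tuple[float, float] = (0.0, 0.0)
    stability: float = 0.8  # cross-wave correlation of the covariate score


@dataclass
class PanelTruth:
    """Ground-truth configuration of a simulated two-wave panel."""

    n: int = 500
    a_frailty: float = 0.6
    a_behaviour: float = 0.5
    c_behaviour_to_frailty: float = -0.126
    c_frailty_to_behaviour: float = 0.167
    r_t1: float = -0.2
    r_resid: float = -0.1
    covariate_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"  # "MCAR" or "MAR"
    behaviour_name: str = "sb"       # scale + sign of the MAR behaviour term
    seed: int = 0

    def validate(self) -> None:
        for name in ("a_frailty", "a_behaviour", "c_behaviour_to_frailty",
                     "c_frailty_to_behaviour", "r_t1", "r_resid"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} = {v} outside (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be MCAR or MAR")
        _residual_scales(self)  # raises on a non-positive residual variance
        cov = implied_covariance(self)
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("implied covariance of (f1, b1, f2, b2) not positive-definite")


def _effect_arrays(truth: PanelTruth):
    names = list(truth.covariate_effects)
    bf1 = np.array([truth.covariate_effects[c].frailty[0] for c in names])
    bf2 = np.array([truth.covariate_effects[c].frailty[1] for c in names])
    bb1 = np.array([truth.covariate_effects[c].behaviour[0] for c in names])
    bb2 = np.array([truth.covariate_effects[c].behaviour[1] for c in names])
    rho = np.array([truth.covariate_effects[c].stability for c in names])
    return names, bf1, bf2, bb1, bb2, rho


def _residual_scales(truth: PanelTruth):
    """Residual SDs and correlations keeping every panel variable at unit
    variance; raises naming the offending parameter when impossible."""
    names, bf1, bf2, bb1, bb2, rho = _effect_arrays(truth)
    s_f1_sq = 1.0 - float(bf1 @ bf1)
    s_b1_sq = 1.0 - float(bb1 @ bb1)
    if s_f1_sq <= 0:
        raise ValueError("covariate_effects on wave-1 frailty leave non-positive residual variance")
    if s_b1_sq <= 0:
        raise ValueError("covariate_effects on wave-1 behaviour leave non-positive residual variance")
    s_f1, s_b1 = np.sqrt(s_f1_sq), np.sqrt(s_b1_sq)
    r1 = (truth.r_t1 - float(bf1 @ bb1)) / (s_f1 * s_b1)
    if not -1.0 < r1 < 1.0:
        raise ValueError("r_t1 incompatible with the wave-1 covariate effects")

    af, ab = truth.a_frailty, truth.a_behaviour
    cbf, cfb = truth.c_behaviour_to_frailty, truth.c_frailty_to_behaviour
    # Cov(f1, c2_j) = bf1_j * rho_j ; Cov(b1, c2_j) = bb1_j * rho_j
    v_f2 = (
        af**2 + cbf**2 + 2 * af * cbf * truth.r_t1
        + float(bf2 @ bf2)
        + 2 * float(bf2 @ (rho * (af * bf1 + cbf * bb1)))
    )
    v_b2 = (
        ab**2 + cfb**2 + 2 * ab * cfb * truth.r_t1
        + float(bb2 @ bb2)
        + 2 * float(bb2 @ (rho * (ab * bb1 + cfb * bf1)))
    )
    s_f2_sq = 1.0 - v_f2
    s_b2_sq = 1.0 - v_b2
    if s_f2_sq <= 0:
        raise ValueError(
            "wave-2 frailty residual variance non-positive; reduce a_frailty / "
            "c_behaviour_to_frailty / covariate effects"
        )
    if s_b2_sq <= 0:
        raise ValueError(
            "wave-2 behaviour residual variance non-positive; reduce a_behaviour / "
            "c_frailty_to_behaviour / covariate effects"
        )
    return s_f1, s_b1, r1, np.sqrt(s_f2_sq), np.sqrt(s_b2_sq)


def implied_covariance(truth: PanelTruth) -> np.ndarray:
    """Population covariance of (frailty_t1, behaviour_t1, frailty_t2,
    behaviour_t2) implied by the structural equations (all unit variance)."""
    names, bf1, bf2, bb1, bb2, rho = _effect_arrays(truth)
    af, ab = truth.a_frailty, truth.a_behaviour
    cbf, cfb = truth.c_behaviour_to_frailty, truth.c_frailty_to_behaviour
    r = truth.r_t1
    s_f1, s_b1, r1, s_f2, s_b2 = _residual_scales(truth)

    c_f1_f2 = af + cbf * r + float(bf2 @ (rho * bf1))
    c_b1_f2 = af * r + cbf + float(bf2 @ (rho * bb1))
    c_f1_b2 = ab * r + cfb + float(bb2 @ (rho * bf1))
    c_b1_b2 = ab + cfb * r + float(bb2 @ (rho * bb1))
    c_f2_b2 = (
        af * ab * r + af * cfb + cbf * ab + cbf * cfb * r
        + float(bf2 @ bb2)
        + af * float(bb2 @ (rho * bf1)) + cbf * float(bb2 @ (rho * bb1))
        + ab * float(bf2 @ (rho * bb1)) + cfb * float(bf2 @ (rho * bf1))
        + s_f2 * s_b2 * truth.r_resid
    )
    return np.array(
        [
            [1.0, r, c_f1_f2, c_f1_b2],
            [r, 1.0, c_b1_f2, c_b1_b2],
            [c_f1_f2, c_b1_f2, 1.0, c_f2_b2],
            [c_f1_b2, c_b1_b2, c_f2_b2, 1.0],
        ]
    )


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort-style covariates at both waves (natural units)."""
    m = _COV_MARGINALS
    age1 = rng.normal(m["age"]["mean"], m["age"]["sd"], n)
    sex = np.where(rng.random(n) < m["sex_female"], "female", "male")
    out = {"age_t1": age1, "age_t2": age1 + m["age"]["gap_years"], "sex": sex}
    for name in ("bmi", "mmse", "wear"):
        spec = m[name]
        (mu1, sd1), (mu2, sd2), rho = spec["t1"], spec["t2"], spec["stability"]
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        out[f"{name}_t1"] = mu1 + sd1 * z1
        out[f"{name}_t2"] = mu2 + sd2 * z2
    for name in ("education", "income", "marital"):
        spec = m[name]
        out[name] = rng.choice(spec["levels"], size=n, p=np.asarray(spec["probs"]) /
                               np.sum(spec["probs"]))
    return pd.DataFrame(out)


def _covariate_scores(truth: PanelTruth, n: int, rng: np.random.Generator):
    """Standardized scores (both waves) for covariates carrying effects."""
    names, *_ = _effect_arrays(truth)
    c1 = np.empty((n, len(names)))
    c2 = np.empty((n, len(names)))
    for j, name in enumerate(names):
        rho = truth.covariate_effects[name].stability
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        c1[:, j], c2[:, j] = z1, z2
    return names, c1, c2


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Logistic intercept such that mean(expit(g0 + lin)) == target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + lin).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# MAR attrition profile: dropouts are older, less educated and more
# sedentary than completers (standardized-logistic slopes)
MAR_SLOPES = {"age": 0.5, "education": -0.5, "behaviour": 0.5}


def generate_panel(truth: PanelTruth, scale: str = "standardized") -> pd.DataFrame:
    """Simulate a wide two-wave panel from a :class:`PanelTruth`.

    ``scale="standardized"`` leaves frailty/behaviour at unit variance so
    the configured coefficients are directly recoverable;
    ``scale="natural"`` maps them to FTS points and min/day (behaviour is
    then left-truncated at zero minutes).  Wave-2 cells of dropouts are
    set to NaN; the boolean ``dropout`` column records the mechanism's
    choices.
    """
    truth.validate()
    if scale not in ("standardized", "natural"):
        raise ValueError("scale must be 'standardized' or 'natural'")
    rng = np.random.default_rng(truth.seed)
    n = truth.n

    cov = _draw_covariates(n, rng)
    names, bf1, bf2, bb1, bb2, rho_c = _effect_arrays(truth)
    _, c1, c2 = _covariate_scores(truth, n, rng)
    s_f1, s_b1, r1, s_f2, s_b2 = _residual_scales(truth)

    u = rng.standard_normal((n, 2))
    u_b = r1 * u[:, 0] + np.sqrt(1 - r1**2) * u[:, 1]
    f1 = c1 @ bf1 + s_f1 * u[:, 0]
    b1 = c1 @ bb1 + s_b1 * u_b

    e = rng.standard_normal((n, 2))
    e_b = truth.r_resid * e[:, 0] + np.sqrt(1 - truth.r_resid**2) * e[:, 1]
    f2 = (
        truth.a_frailty * f1 + truth.c_behaviour_to_frailty * b1
        + c2 @ bf2 + s_f2 * e[:, 0]
    )
    b2 = (
        truth.a_behaviour * b1 + truth.c_frailty_to_behaviour * f1
        + c2 @ bb2 + s_b2 * e_b
    )

    # attrition
    if truth.missing_rate > 0:
        if truth.missing_mechanism == "MCAR":
            drop = rng.random(n) < truth.missing_rate
        else:
            edu_rank = {"none": 0.0, "primary": 1.0, "secondary+": 2.0}
            edu = cov["education"].map(edu_rank).to_numpy()
            edu_z = (edu - edu.mean()) / max(edu.std(), 1e-12)
            age_z = (cov["age_t1"] - cov["age_t1"].mean()) / cov["age_t1"].std()
            sb_sign = 1.0 if truth.behaviour_name == "sb" else -1.0
            lin = (
                MAR_SLOPES["age"] * age_z.to_numpy()
                + MAR_SLOPES["education"] * edu_z
                + MAR_SLOPES["behaviour"] * sb_sign * b1
            )
            g0 = _calibrate_intercept(lin, truth.missing_rate)
            drop = rng.random(n) < expit(g0 + lin)
    else:
        drop = np.zeros(n, dtype=bool)

    if scale == "natural":
        key = truth.behaviour_name if truth.behaviour_name in NATURAL_SCALES else "sb"
        mf1, sf1 = NATURAL_SCALES["frailty"]["t1"]
        mf2, sf2 = NATURAL_SCALES["frailty"]["t2"]
        mb1, sb1_ = NATURAL_SCALES[key]["t1"]
        mb2, sb2_ = NATURAL_SCALES[key]["t2"]
        f1 = mf1 + sf1 * f1
        f2 = mf2 + sf2 * f2
        b1 = mb1 + sb1_ * b1
        b2 = mb2 + sb2_ * b2
        f1 = np.clip(f1, 0.0, 100.0)
        f2 = np.clip(f2, 0.0, 100.0)
        b1 = np.maximum(b1, 0.0)
        b2 = np.maximum(b2, 0.0)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "frailty_t1": f1,
            "behaviour_t1": b1,
            "frailty_t2": np.where(drop, np.nan, f2),
            "behaviour_t2": np.where(drop, np.nan, b2),
            "dropout": drop,
        }
    )
    for c in cov.columns:
        df[c] = cov[c].to_numpy()
    # dropouts have no wave-2 measurements at all
    for c in ("age_t2", "bmi_t2", "mmse_t2", "wear_t2"):
        df.loc[drop, c] = np.nan
    return df


# ---------------------------------------------------------------------------
# accelerometer epoch streams
# ---------------------------------------------------------------------------

@dataclass
class EpochProfile:
    """Configuration of a simulated 1-min epoch stream (one participant).

    The daily pattern repeats over ``days``: zeros outside the wear
    window [wear_start, wear_end), non-wear blocks of zeros inside it,
    MVPA bouts and spike minutes at fixed counts, and a sub-100
    sedentary background (log-normal, clipped to [1, 99] so worn
    sedentary minutes are never confused with device-off zeros).
    """

    participant_id: str = "P000000"
    days: int = 7
    wear_start: int = 480            # 08:00
    wear_end: int = 1380             # 23:00
    nonwear_blocks: list[tuple[int, int]] = field(default_factory=list)  # (start, duration>=60)
    mvpa_bouts: list[tuple[int, int, int]] = field(default_factory=list)  # (start, dur, counts>=1952)
    light_bouts: list[tuple[int, int, int]] = field(default_factory=list)  # (start, dur, 100<=counts<1952)
    spike_minutes: list[int] = field(default_factory=list)
    spike_counts: int = 25_000
    sedentary_level: tuple[float, float] = (3.2, 0.8)  # lognormal (mu, sigma) of counts
    seed: int = 0

    def validate(self, window_min: int = 60, allowance_max: int = 2) -> None:
        if not 0 <= self.wear_start < self.wear_end <= 1440:
            raise ValueError("wear window must satisfy 0 <= start < end <= 1440")
        if 0 < self.wear_start < window_min or 0 < 1440 - self.wear_end < window_min:
            raise ValueError("off-wrist margins shorter than the non-wear window are ambiguous")
        spans = []
        for start, dur in self.nonwear_blocks:
            if dur < window_min:
                raise ValueError(f"non-wear block at {start} shorter than {window_min} min")
            if not (self.wear_start <= start and start + dur <= self.wear_end):
                raise ValueError(f"non-wear block at {start} outside the wear window")
            spans.append(("nonwear", start, start + dur))
        for start, dur, level in self.mvpa_bouts:
            if level < 1952:
                raise ValueError("MVPA bout counts must be >= 1952")
            if not (self.wear_start <= start and start + dur <= self.wear_end):
                raise ValueError(f"bout at {start} outside the wear window")
            spans.append(("bout", start, start + dur))
        for start, dur, level in self.light_bouts:
            if not 100 <= level < 1952:
                raise ValueError("light bout counts must lie in [100, 1952)")
            if not (self.wear_start <= start and start + dur <= self.wear_end):
                raise ValueError(f"light bout at {start} outside the wear window")
            spans.append(("light", start, start + dur))
        for minute in self.spike_minutes:
            if not self.wear_start <= minute < self.wear_end:
                raise ValueError(f"spike minute {minute} outside the wear window")
            spans.append(("spike", minute, minute + 1))
        spans.sort(key=lambda s: s[1])
        for (k1, a1, b1), (k2, a2, b2) in zip(spans, spans[1:]):
            if b1 > a2:
                raise ValueError(f"overlapping segments: {k1}[{a1},{b1}) and {k2}[{a2},{b2})")
            if k1 == k2 == "nonwear" and a2 - b1 <= allowance_max:
                raise ValueError(
                    "non-wear blocks closer than the interruption allowance would merge"
                )


def random_epoch_profile(seed: int, participant_id: str = "P000000") -> EpochProfile:
    """A random but internally consistent epoch profile (for oracle tests)."""
    rng = np.random.default_rng(seed)
    wear_start = int(rng.integers(6, 10)) * 60
    wear_end = int(rng.integers(21, 24)) * 60
    blocks = []
    if rng.random() < 0.7:
        start = int(rng.integers(wear_start + 10, wear_end - 200))
        blocks.append((start, int(rng.integers(60, 120))))
    bouts = []
    cursor = wear_start
    for _ in range(int(rng.integers(0, 3))):
        cursor += int(rng.integers(10, 120))
        dur = int(rng.integers(5, 40))
        bout = (cursor, dur, int(rng.integers(1952, 6000)))
        span_ok = all(
            bout[0] + bout[1] <= b[0] or bout[0] >= b[0] + b[1] for b in blocks
        ) and bout[0] + bout[1] <= wear_end
        if span_ok:
            bouts.append(bout)
        cursor += dur
    profile = EpochProfile(
        participant_id=participant_id,
        days=int(rng.integers(4, 8)),
        wear_start=wear_start,
        wear_end=wear_end,
        nonwear_blocks=blocks,
        mvpa_bouts=bouts,
        spike_minutes=[],
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    profile.validate()
    return profile


def generate_epochs(profile: EpochProfile, start_date: str = "2012-07-01"):
    """Simulate the epoch stream and return (epochs, truth).

    ``epochs`` has columns ``participant_id, date, minute, counts``;
    ``truth`` is a per-day DataFrame with the generator's ground-truth
    wear/SB/MVPA minutes and the per-day wear mask in ``truth.attrs``.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    dates = pd.date_range(start_date, periods=profile.days, freq="D").date
    frames = []
    truth_rows = []
    masks = {}
    mu, sigma = profile.sedentary_level
    for day in dates:
        counts = np.zeros(1440, dtype=np.int64)
        worn = np.zeros(1440, dtype=bool)
        worn[profile.wear_start : profile.wear_end] = True
        for start, dur in profile.nonwear_blocks:
            worn[start : start + dur] = False
        n_worn = int(worn.sum())
        sed = np.clip(np.round(rng.lognormal(mu, sigma, n_worn)), 1, 99).astype(np.int64)
        counts[worn] = sed
        for start, dur, level in profile.mvpa_bouts:
            counts[start : start + dur] = level
        for start, dur, level in profile.light_bouts:
            counts[start : start + dur] = level
        for minute in profile.spike_minutes:
            counts[minute] = profile.spike_counts
        sb_true = int((counts[worn] < 100).sum())
        mvpa_true = int((counts[worn] >= 1952).sum())
        truth_rows.append(
            {
                "participant_id": profile.participant_id,
                "day": day,
                "wear_min": n_worn,
                "nonwear_min": 1440 - n_worn,
                "sb_min": sb_true,
                "mvpa_min": mvpa_true,
                "has_spike": bool((counts[worn] > 20_000).any()),
            }
        )
        masks[day] = worn
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": profile.participant_id,
                    "date": str(day),
                    "minute": np.arange(1440),
                    "counts": counts,
                }
            )
        )
    epochs = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["wear_masks"] = masks
    return epochs, truth


# ---------------------------------------------------------------------------
# FTS item batteries
# ---------------------------------------------------------------------------

# plausible raw-value marginals per item (continuous draws)
_ITEM_MARGINALS = {
    "bmi": (30.8, 4.6),
    "waist": (102.0, 12.0),
    "weight_loss": (2.0, 2.5),
    "albumin": (4.1, 0.35),
    "pase": (95.0, 45.0),
    "verbal_fluency": (14.0, 5.0),
    "balance": None,           # categorical 0..4
    "ankle_brachial": (1.05, 0.15),
    "grip": (24.0, 9.0),
    "knee_extension": (14.0, 6.0),
    "chair_stand": None,       # count, with zeros
    "gait_time": (4.5, 1.8),
}


def generate_fts_battery(
    n: int,
    cutpoints: dict[str, tuple[float, float, float, float]] | None = None,
    seed: int = 0,
    n_missing_items: int = 0,
    specs=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw 12-item battery table for ``n`` participants.

    If ``cutpoints`` is given, each quintile-scored item's raw values are
    drawn with uniform quintile membership and then uniformly within the
    membership bin, so the population quintiles match the supplied
    boundaries; the returned truth table records the true bin per value.
    Otherwise raw values follow plausible continuous marginals and the
    scorer's own population quintiles apply.  ``n_missing_items`` masks
    that many randomly chosen items per participant.
    """
    if specs is None:
        specs = fts_mod.default_item_specs()
    rng = np.random.default_rng(seed)
    pids = [f"P{i:06d}" for i in range(n)]
    rows = []
    truth_rows = []
    for item_id, spec in specs.items():
        if cutpoints is not None and item_id in cutpoints:
            cp = np.asarray(cutpoints[item_id], dtype=float)
            if np.unique(cp).size < 4:
                raise ValueError(f"{item_id}: fewer than 5 distinct values per quintile bin")
            width = np.median(np.diff(cp))
            edges = np.concatenate([[cp[0] - width], cp, [cp[3] + width]])
            bins = rng.integers(0, 5, n)
            vals = rng.uniform(edges[bins], edges[bins + 1])
            true_bin = bins
        elif item_id == "balance":
            vals = rng.integers(0, 5, n).astype(float)
            true_bin = None
        elif item_id == "chair_stand":
            vals = np.maximum(np.round(rng.normal(10, 4, n)), 0.0)
            true_bin = None
        else:
            mean, sd = _ITEM_MARGINALS[item_id]
            vals = rng.normal(mean, sd, n)
            if item_id in ("weight_loss", "pase", "verbal_fluency", "gait_time"):
                vals = np.maximum(vals, 0.0)
            true_bin = None
        rows.append(pd.DataFrame(
            {"participant_id": pids, "item_id": item_id, "raw_value": vals}
        ))
        if true_bin is not None:
            truth_rows.append(pd.DataFrame(
                {"participant_id": pids, "item_id": item_id, "true_bin": true_bin}
            ))
    raw = pd.concat(rows, ignore_index=True)
    truth = (pd.concat(truth_rows, ignore_index=True)
             if truth_rows else pd.DataFrame(columns=["participant_id", "item_id", "true_bin"]))

    if n_missing_items > 0:
        item_list = list(specs)
        masked = []
        for pid in pids:
            for item in rng.choice(item_list, size=n_missing_items, replace=False):
                masked.append((pid, item))
        mask_idx = raw.set_index(["participant_id", "item_id"]).index.isin(masked)
        raw = raw.loc[~mask_idx].reset_index(drop=True)
    return raw, truth


def extreme_battery(specs=None, which: str = "worst") -> pd.DataFrame:
    """A single-participant battery at every item's best or worst raw value.

    Requires specs with cutpoints already set; values are placed beyond
    the outer boundaries (and chair-stand 0 for the worst case).
    """
    if specs is None:
        raise ValueError("extreme_battery needs specs with cutpoints")
    rows = []
    for item_id, spec in specs.items():
        cp = np.asarray(spec.cutpoints, dtype=float)
        below, above = cp[0] - 1.0, cp[3] + 1.0
        if which == "worst":
            val = 0.0 if spec.zero_raw_score is not None else (
                below if spec.higher_is_better else above)
        elif which == "best":
            val = above if spec.higher_is_better else below
        else:
            raise ValueError("which must be 'best' or 'worst'")
        rows.append({"participant_id": "P000000", "item_id": item_id, "raw_value": val})
    return pd.DataFrame(rows)
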