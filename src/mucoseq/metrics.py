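"""Quantitative barrier and physiology readouts.

Imaging-derived bacteria-to-epithelium distances (per-mouse summaries and
taxa distance ratios), ex vivo mucus thickness/growth-rate estimates with
paired comparisons, and the chemically induced colitis readouts (disease
activity index and ulceration percentage).

Measurement tables are long format with columns ``mouse_id``, ``group``,
``variable`` ({distance, thickness}), ``probe`` (FISH probe or ex vivo
condition), ``time`` (minutes; thickness only) and ``value`` (μm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    MeasurementValidationError,
    PairingError,
)

MIN_DISTANCE_MEASUREMENTS = 25  # imaging protocol validity rule


# ---------------------------------------------------------------------------
# distances


def mouse_distance_summary(
    table: pd.DataFrame,
    statistic: str = "mean",
    min_per_mouse: int = MIN_DISTANCE_MEASUREMENTS,
    allow_below_min: bool = False,
) -> pd.DataFrame:
    """Per-mouse (and per-probe) summary of bacteria-to-epithelium distances.

    Requires at least ``min_per_mouse`` measurements for every
    (mouse, probe) cell; offenders are listed in the error.  Set
    ``allow_below_min=True`` to downgrade the failure to a warning.
    Returns one row per (mouse, probe) with columns ``group`` and ``value``.
    """
    dist = table[table["variable"] == "distance"]
    if dist.empty:
        raise MeasurementValidationError("no distance rows in the table")
    counts = dist.groupby(["mouse_id", "probe"]).size()
    low = counts[counts < min_per_mouse]
    if not low.empty:
        offenders = ", ".join(
            f"{m}/{p} (n={n})" for (m, p), n in low.items()
        )
        msg = (
            f"fewer than {min_per_mouse} distance measurements for: {offenders}"
        )
        if allow_below_min:
            warnings.warn(msg, stacklevel=2)
        else:
            raise MeasurementValidationError(msg)
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = (
        dist.groupby(["mouse_id", "probe"])
        .agg(group=("group", "first"), value=("value", statistic))
        .reset_index()
    )
    return agg


def taxa_distance_ratio(
    table: pd.DataFrame, probe_num: str, probe_den: str
) -> pd.DataFrame:
    """Per-mouse ratio of mean distances between two FISH probes.

    For untreated animals the Gram-positive *Clostridia* sit closer to the
    epithelium than *Gammaproteobacteria*, so the Clostridia/Gamma ratio is
    below 1; treatments that invert the spatial organisation push it above.
    A zero denominator mean yields NaN with a warning.
    """
    dist = table[table["variable"] == "distance"]
    means = dist.groupby(["mouse_id", "probe"])["value"].mean().unstack()
    for probe in (probe_num, probe_den):
        if probe not in means.columns or means[probe].isna().any():
            missing = (
                list(means.index[means[probe].isna()])
                if probe in means.columns
                else list(means.index)
            )
            raise MeasurementValidationError(
                f"probe {probe!r} missing for mice: {missing}"
            )
    den = means[probe_den]
    if (den == 0).any():
        warnings.warn(
            f"zero denominator mean for mice {list(means.index[den == 0])}; "
            "ratio undefined (NaN)",
            stacklevel=2,
        )
    ratio = means[probe_num] / den.replace(0, np.nan)
    groups = dist.groupby("mouse_id")["group"].first()
    return pd.DataFrame(
        {"group": groups.loc[ratio.index], "ratio": ratio}
    ).reset_index()


# ---------------------------------------------------------------------------
# mucus secretion


def mucus_growth_rate(series: pd.DataFrame) -> float:
    """Least-squares slope (μm/min) of thickness versus time for one tissue.

    The change in mucus thickness per minute over the recording window;
    on noiseless data this equals the endpoint difference divided by the
    elapsed time, and it is robust on noisy series.
    """
    t = series["time"].to_numpy(dtype=float)
    v = series["value"].to_numpy(dtype=float)
    if np.unique(t).size < 2:
        raise InsufficientDataError(
            "growth rate needs at least 2 distinct time points"
        )
    slope, _ = np.polyfit(t, v, 1)
    return float(slope)


def growth_rates_by_tissue(table: pd.DataFrame) -> pd.DataFrame:
    """Growth rate for every (mouse, condition) thickness series."""
    thick = table[table["variable"] == "thickness"]
    if thick.empty:
        raise MeasurementValidationError("no thickness rows in the table")
    rows = [
        {"mouse_id": m, "group": g, "rate": mucus_growth_rate(sub)}
        for (m, g), sub in thick.groupby(["mouse_id", "group"])
    ]
    return pd.DataFrame(rows)


def paired_secretion_comparison(
    rates: pd.DataFrame,
    control: str = "control",
    treated: str = "treated",
) -> dict:
    """Paired control/treated comparison of per-animal secretion rates.

    ``rates`` holds one row per tissue with columns ``mouse_id``, ``group``
    (condition) and ``rate``; both tissues of a pair come from the same
    animal.  Returns per-pair differences (treated − control) and ratios
    (control / treated), their means, and the two-sided paired t-test
    p-value.  All-zero differences (identical pairs) give p = 1.
    """
    wide = rates.pivot(index="mouse_id", columns="group", values="rate")
    for cond in (control, treated):
        if cond not in wide.columns:
            raise PairingError(f"condition {cond!r} absent from rates table")
    if wide[[control, treated]].isna().any(axis=None):
        bad = list(wide.index[wide[[control, treated]].isna().any(axis=1)])
        raise PairingError(f"unpaired animals: {bad}")
    if wide.shape[0] < 3:
        raise InsufficientDataError("paired comparison needs >= 3 complete pairs")

    diff = wide[treated] - wide[control]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = wide[control] / wide[treated]
    if np.allclose(diff, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(wide[treated], wide[control])
    return {
        "n_pairs": int(wide.shape[0]),
        "differences": diff,
        "ratios": ratio,
        "mean_difference": float(diff.mean()),
        "mean_ratio": float(ratio.mean()),
        "t_statistic": float(t_stat),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# colitis


@dataclass(frozen=True)
class ColitisRecord:
    """One mouse-day of colitis observations.

    ``weight_change_pct`` is the percent weight change relative to the
    initial weight (negative = loss; −12 means 12% lost).  Areas are in any
    consistent unit.
    """

    mouse_id: str
    day: int
    weight_change_pct: float
    stool: str
    bleeding: str
    ulcer_area: float | None = None
    healthy_area: float | None = None

    def __post_init__(self) -> None:
        for name in ("ulcer_area", "healthy_area"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")


#: 0–4 subscores of the disease activity index (standard DSS scheme)
STOOL_SCORES = {"normal": 0, "solid": 0, "loose": 2, "diarrhea": 4}
BLEEDING_SCORES = {"none": 0, "occult": 2, "gross": 4}
#: (exclusive upper bound of weight-loss %, score)
WEIGHT_LOSS_BINS = ((1.0, 0), (5.0, 1), (10.0, 2), (20.0, 3), (np.inf, 4))


def weight_loss_score(weight_change_pct: float) -> int:
    loss = max(0.0, -float(weight_change_pct))
    for bound, score in WEIGHT_LOSS_BINS:
        if loss < bound:
            return score
    return 4  # pragma: no cover


def dai_score(
    record: ColitisRecord,
    stool_scores: dict = STOOL_SCORES,
    bleeding_scores: dict = BLEEDING_SCORES,
) -> int:
    """Disease activity index: weight loss, stool consistency and rectal
    bleeding each scored 0–4 and summed (range 0–12)."""
    try:
        s_stool = stool_scores[record.stool]
    except KeyError:
        raise MeasurementValidationError(
            f"unknown stool category {record.stool!r}"
        ) from None
    try:
        s_bleed = bleeding_scores[record.bleeding]
    except KeyError:
        raise MeasurementValidationError(
            f"unknown bleeding category {record.bleeding!r}"
        ) from None
    return weight_loss_score(record.weight_change_pct) + s_stool + s_bleed


def ulceration_percent(ulcer_area: float, healthy_area: float) -> float:
    """100 · ulcerated / (ulcerated + healthy) area."""
    if ulcer_area < 0 or healthy_area < 0:
        raise ValueError("areas must be nonnegative")
    total = ulcer_area + healthy_area
    if total == 0:
        raise MeasurementValidationError(
            "both areas are zero; ulceration percent undefined"
        )
    return 100.0 * ulcer_area / total


# ---------------------------------------------------------------------------
# reporting conveniences


def group_comparison(values: pd.Series, groups: pd.Series) -> dict:
    """Two-sided test across group means for a per-mouse summary.

    Two groups → Student's t test; more than two → one-way ANOVA
    (the conventions of the figure legends this mirrors).
    """
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups to compare")
    samples = [values[groups == g].to_numpy(dtype=float) for g in levels]
    if len(levels) == 2:
        stat, p = stats.ttest_ind(samples[0], samples[1])
        test = "student_t"
    else:
        stat, p = stats.f_oneway(*samples)
        test = "one_way_anova"
    return {
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "group_means": {g: float(np.mean(s)) for g, s in zip(levels, samples)},
        "group_n": {g: int(s.size) for g, s in zip(levels, samples)},
    }
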