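"""Classification of individuals into WHO-guideline activity categories.

Weekly minutes of vigorous activity, moderate activity and walking are
collapsed into *moderate-equivalent minutes* (vigorous counts double, walking
counts half) and compared against the 150 / 300 min guideline thresholds for
adults aged 18-64.  Four categories result:

* ``non_active``     -- no activity of any kind at all,
* ``below_healthy``  -- active but under 150 moderate-equivalent min/week,
* ``healthy``        -- in [150, 300) min/week (meets the guidelines),
* ``extra_healthy``  -- 300+ min/week (additional health benefits).

Individual classifications are aggregated to regional rate profiles
(percentage of the eligible, i.e. working-age, respondents in each category).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default guideline thresholds, moderate-equivalent minutes per week
DEFAULT_THRESHOLDS: Tuple[float, float] = (150.0, 300.0)
#: default working-age bracket, inclusive on both ends
DEFAULT_AGE_RANGE: Tuple[int, int] = (18, 64)

MICRODATA_COLUMNS = [
    "respondent_id",
    "region_id",
    "age",
    "vigorous_min",
    "moderate_min",
    "walking_min",
]

PROFILE_RATE_COLUMNS = [
    "rate_non_active",
    "rate_below_healthy",
    "rate_healthy",
    "rate_extra_healthy",
]


class ActivityClass(enum.IntEnum):
    """Activity category ordered from least to most active."""

    NON_ACTIVE = 0
    BELOW_HEALTHY = 1
    HEALTHY = 2
    EXTRA_HEALTHY = 3

    @property
    def label(self) -> str:
        return _CLASS_LABELS[int(self)]


_CLASS_LABELS = ["non_active", "below_healthy", "healthy", "extra_healthy"]

#: column order used throughout for class shares / rates
CLASS_LABELS = tuple(_CLASS_LABELS)


@dataclass(frozen=True)
class ActivityRecord:
    """One respondent's weekly activity minutes plus region and age."""

    respondent_id: str
    region_id: str
    age: int
    vigorous_min: float
    moderate_min: float
    walking_min: float

    def __post_init__(self) -> None:
        _validate_minutes(self.vigorous_min, self.moderate_min, self.walking_min)
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")


def _validate_minutes(vigorous: float, moderate: float, walking: float) -> None:
    for name, value in (
        ("vigorous_min", vigorous),
        ("moderate_min", moderate),
        ("walking_min", walking),
    ):
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {value}")


def moderate_equivalent_minutes(
    vigorous_min, moderate_min, walking_min
):
    """Weekly moderate-equivalent minutes: ``2*vigorous + moderate + 0.5*walking``.

    Accepts scalars or numpy arrays.  A vigorous minute is worth two moderate
    minutes; a walking minute is worth half a moderate minute.
    """
    v = np.asarray(vigorous_min, dtype=float)
    m = np.asarray(moderate_min, dtype=float)
    w = np.asarray(walking_min, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(~np.isfinite(m)) or np.any(~np.isfinite(w)):
        raise ValueError("minute fields must be finite")
    if np.any(v < 0) or np.any(m < 0) or np.any(w < 0):
        raise ValueError("minute fields must be non-negative")
    out = 2.0 * v + m + 0.5 * w
    if out.ndim == 0:
        return float(out)
    return out


def classify_minutes(
    vigorous_min,
    moderate_min,
    walking_min,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
):
    """Vectorized four-way classification from the three raw minute fields.

    ``non_active`` requires *exactly zero* minutes in all three activity
    types (walking counts as activity); otherwise the moderate-equivalent
    total is binned into [0, lower), [lower, upper), [upper, inf).
    Returns integer codes per :class:`ActivityClass`.
    """
    lower, upper = thresholds
    if not 0 < lower < upper:
        raise ValueError(f"thresholds must satisfy 0 < lower < upper, got {thresholds}")
    v = np.asarray(vigorous_min, dtype=float)
    m = np.asarray(moderate_min, dtype=float)
    w = np.asarray(walking_min, dtype=float)
    mem = moderate_equivalent_minutes(v, m, w)
    mem = np.asarray(mem, dtype=float)
    codes = np.where(
        (v == 0) & (m == 0) & (w == 0),
        ActivityClass.NON_ACTIVE,
        np.where(
            mem < lower,
            ActivityClass.BELOW_HEALTHY,
            np.where(mem < upper, ActivityClass.HEALTHY, ActivityClass.EXTRA_HEALTHY),
        ),
    )
    if codes.ndim == 0:
        return int(codes)
    return codes.astype(int)


def classify_individual(
    record: ActivityRecord,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
) -> ActivityClass:
    """Classify a single :class:`ActivityRecord`."""
    code = classify_minutes(
        record.vigorous_min, record.moderate_min, record.walking_min, thresholds
    )
    return ActivityClass(code)


def classify_frame(
    microdata: pd.DataFrame,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Return a copy of ``microdata`` with ``activity_class`` label column added."""
    codes = classify_minutes(
        microdata["vigorous_min"].to_numpy(),
        microdata["moderate_min"].to_numpy(),
        microdata["walking_min"].to_numpy(),
        thresholds,
    )
    out = microdata.copy()
    out["activity_class"] = np.asarray(_CLASS_LABELS, dtype=object)[np.atleast_1d(codes)]
    return out


def filter_working_age(
    microdata: pd.DataFrame,
    age_range: Tuple[int, int] = DEFAULT_AGE_RANGE,
) -> Tuple[pd.DataFrame, Tuple[int, int]]:
    """Restrict to respondents inside the closed age bracket.

    Returns the filtered frame and the (before, after) row counts; the
    reduction is also logged so the sample-restriction audit trail survives.
    """
    lo, hi = age_range
    if lo > hi:
        raise ValueError(f"age range lower bound exceeds upper bound: {age_range}")
    before = len(microdata)
    kept = microdata[(microdata["age"] >= lo) & (microdata["age"] <= hi)]
    after = len(kept)
    logger.info(
        "age filter [%d, %d]: %d -> %d respondents (%d removed)",
        lo, hi, before, after, before - after,
    )
    return kept.reset_index(drop=True), (before, after)


def regionalize(
    classified: pd.DataFrame,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Aggregate classified (already age-filtered) microdata to regional profiles.

    Per region each rate is ``100 * count_in_class / n_eligible`` (plain
    unweighted proportions).  Output columns:
    ``region_id, rate_non_active, rate_below_healthy, rate_healthy,
    rate_extra_healthy, n_eligible``.  Regions with zero eligible respondents
    cannot appear (they have no rows); an empty input yields an empty frame
    with a warning.
    """
    if "activity_class" not in classified.columns:
        classified = classify_frame(classified, thresholds)
    if len(classified) == 0:
        logger.warning("regionalize called with no records; emitting empty profile table")
        return pd.DataFrame(
            columns=["region_id", *PROFILE_RATE_COLUMNS, "n_eligible"]
        )
    counts = (
        classified.groupby("region_id")["activity_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CLASS_LABELS), fill_value=0)
    )
    n_eligible = counts.sum(axis=1)
    rates = 100.0 * counts.div(n_eligible, axis=0)
    profiles = pd.DataFrame(
        {
            "region_id": counts.index.astype(str),
            "rate_non_active": rates["non_active"].to_numpy(),
            "rate_below_healthy": rates["below_healthy"].to_numpy(),
            "rate_healthy": rates["healthy"].to_numpy(),
            "rate_extra_healthy": rates["extra_healthy"].to_numpy(),
            "n_eligible": n_eligible.to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    return profiles


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    """Convert a sequence of :class:`ActivityRecord` into the microdata frame."""
    rows = [
        (r.respondent_id, r.region_id, r.age, r.vigorous_min, r.moderate_min, r.walking_min)
        for r in records
    ]
    return pd.DataFrame(rows, columns=MICRODATA_COLUMNS)
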