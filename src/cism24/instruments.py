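"""Questionnaire scoring: PHQ-9, screen time, and composition assembly.

Raw survey records carry nine PHQ-9 depression items, short-form physical
activity recall fields (daily walking, moderate and vigorous activity, and
sedentary minutes), a sleep-duration field, and separate school-day and
weekend screen-time fields.  This module turns them into analytic records:
a PHQ-9 total with its severity band and a five-part daily composition
(mvpa, lpa, nsst, slp, st) closed to 1440 minutes.

Construction rules:

* MVPA = moderate + vigorous minutes (the two intensities are combined).
* LPA = walking minutes.
* ST = time-weighted daily screen average, (5*school_day + 2*weekend)/7.
* NSST = total sedentary minutes minus ST, floored at ``zero_floor``
  (screen use is carved out of overall sedentary time).
* SLP = reported sleep minutes.

Compositional analysis needs strictly positive parts, so any
non-positive part is replaced by ``zero_floor`` (default 1 minute) before
the five parts are multiplicatively closed to the day total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._reference import DAY_MINUTES, PARTS
from .coda import Composition, close

logger = logging.getLogger(__name__)

__all__ = [
    "SEVERITY_BANDS",
    "SEVERITY_LEVELS",
    "RawQuestionnaire",
    "SubjectRecord",
    "phq9_score",
    "phq9_severity",
    "average_daily_screen_time",
    "assemble_composition",
    "build_analytic_table",
]

#: PHQ-9 severity bands: total-score ranges (inclusive).
SEVERITY_BANDS = {
    "none": (0, 4),
    "mild": (5, 9),
    "moderate": (10, 14),
    "severe": (15, 27),
}

SEVERITY_LEVELS = tuple(SEVERITY_BANDS)

#: Raw-CSV column names for the minute fields, in assembly order.
RAW_MINUTE_COLUMNS = (
    "walk_min_day",
    "mpa_min_day",
    "vpa_min_day",
    "sedentary_min_day",
    "sleep_min_day",
    "screen_weekday_min",
    "screen_weekend_min",
)

PHQ9_COLUMNS = tuple(f"phq9_item{i}" for i in range(1, 10))


@dataclass(frozen=True)
class RawQuestionnaire:
    """One subject's raw survey fields, validated on construction."""

    phq9_items: tuple[int, ...]
    walk_min_day: float
    mpa_min_day: float
    vpa_min_day: float
    sedentary_min_day: float
    sleep_min_day: float
    screen_weekday_min: float
    screen_weekend_min: float
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.phq9_items) != 9:
            raise ValueError(f"expected 9 PHQ-9 items, got {len(self.phq9_items)}")
        for i, item in enumerate(self.phq9_items):
            if item not in (0, 1, 2, 3):
                raise ValueError(f"PHQ-9 item {i + 1} out of range 0..3: {item!r}")
        for name in RAW_MINUTE_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """An analytic record: closed composition, depression score, covariates."""

    composition: Composition
    depression_score: float
    severity: str
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.depression_score <= 27:
            raise ValueError(
                f"depression score out of range 0..27: {self.depression_score}"
            )
        if self.severity not in SEVERITY_BANDS:
            raise ValueError(f"unknown severity {self.severity!r}")


def phq9_severity(total: int) -> str:
    """Severity band of a PHQ-9 total (0-4 none, 5-9 mild, 10-14 moderate,
    15-27 severe)."""
    for band, (lo, hi) in SEVERITY_BANDS.items():
        if lo <= total <= hi:
            return band
    raise ValueError(f"PHQ-9 total out of range 0..27: {total}")


def phq9_score(items: Sequence[int]) -> tuple[int, str]:
    """Score the nine PHQ-9 items: (total 0..27, severity band)."""
    items = list(items)
    if len(items) != 9:
        raise ValueError(f"expected 9 PHQ-9 items, got {len(items)}")
    for i, item in enumerate(items):
        if item not in (0, 1, 2, 3):
            raise ValueError(f"PHQ-9 item {i + 1} out of range 0..3: {item!r}")
    total = int(sum(items))
    return total, phq9_severity(total)


def average_daily_screen_time(weekday_min: float, weekend_min: float) -> float:
    """Time-weighted daily screen minutes: (5*weekday + 2*weekend) / 7."""
    for name, v in (("weekday_min", weekday_min), ("weekend_min", weekend_min)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
    return (5.0 * weekday_min + 2.0 * weekend_min) / 7.0


def assemble_composition(
    raw: RawQuestionnaire,
    zero_floor: float = 1.0,
    total: float = DAY_MINUTES,
) -> Composition:
    """Build the closed five-part composition from raw minute fields.

    Any part that comes out non-positive is replaced by ``zero_floor``
    minutes before closure, keeping the vector strictly positive as the
    log-ratio machinery requires.
    """
    if zero_floor <= 0:
        raise ValueError(f"zero_floor must be positive, got {zero_floor}")
    st = average_daily_screen_time(raw.screen_weekday_min, raw.screen_weekend_min)
    parts = {
        "mvpa": raw.mpa_min_day + raw.vpa_min_day,
        "lpa": raw.walk_min_day,
        "nsst": raw.sedentary_min_day - st,
        "slp": raw.sleep_min_day,
        "st": st,
    }
    floored = np.array([max(parts[p], zero_floor) for p in PARTS])
    if all(parts[p] <= 0 for p in PARTS):
        raise ValueError("all activity parts are zero; record cannot be assembled")
    return close(floored, PARTS, total)


def build_analytic_table(
    raw: pd.DataFrame,
    covariates: Sequence[str] = (),
    zero_floor: float = 1.0,
    total: float = DAY_MINUTES,
) -> tuple[pd.DataFrame, int]:
    """Score a raw survey table into the analytic schema, complete-case.

    Rows with any missing or invalid required field are dropped and counted;
    the drop count is logged and returned alongside the analytic frame,
    whose columns are the five part columns, ``phq9_total``, ``severity``,
    and the requested covariates.
    """
    required = list(PHQ9_COLUMNS) + list(RAW_MINUTE_COLUMNS) + list(covariates)
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw table is missing required columns: {missing_cols}")

    rows: list[dict] = []
    dropped = 0
    for idx, row in raw.iterrows():
        try:
            if row[required].isna().any():
                raise ValueError("missing required field")
            rq = RawQuestionnaire(
                phq9_items=tuple(int(row[c]) for c in PHQ9_COLUMNS),
                **{c: float(row[c]) for c in RAW_MINUTE_COLUMNS},
            )
            total_score, severity = phq9_score(rq.phq9_items)
            comp = assemble_composition(rq, zero_floor=zero_floor, total=total)
        except (ValueError, TypeError) as exc:
            logger.info("dropping row %s: %s", idx, exc)
            dropped += 1
            continue
        rec = comp.asdict()
        rec["phq9_total"] = total_score
        rec["severity"] = severity
        for c in covariates:
            rec[c] = row[c]
        rows.append(rec)

    if dropped:
        logger.warning("dropped %d of %d rows (complete-case)", dropped, len(raw))
    out = pd.DataFrame(rows, columns=list(PARTS) + ["phq9_total", "severity"]
                       + list(covariates))
    return out, dropped
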