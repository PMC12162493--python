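"""Time-to-onset (TTO): days from therapy start to event onset.

TTO is the calendar-day difference between the report's event date
(EVENT_DT) and the primary-suspect drug's therapy start date (START_DT).
Reports with missing, partial or unreasonable dates (negative interval, or a
date before 1900-01-01 or after the extraction date) are excluded, each with
a recorded reason.  Same-day onset (0 days) is kept: an infusion reaction on
the day of administration is clinically real.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import AdverseEventReport

log = logging.getLogger(__name__)

DEFAULT_EXTRACTION_DATE = date(2024, 6, 30)
_MIN_DATE = date(1900, 1, 1)

#: Exclusion reasons, in precedence order (first applicable wins).
EXCLUSION_REASONS = ("none", "missing_event", "missing_start", "partial_date",
                     "negative_interval", "out_of_range")


@dataclass(frozen=True)
class TimeToOnsetRecord:
    primaryid: str
    drug: str | None
    sex: str | None
    tto_days: int | None
    exclusion_reason: str

    @property
    def included(self) -> bool:
        return self.exclusion_reason == "none"


def _parse_date(s: str) -> tuple[date | None, str]:
    """Return (date, status) with status in full/partial/missing."""
    s = (s or "").strip()
    if not s:
        return None, "missing"
    if len(s) == 8 and s.isdigit():
        try:
            return date(int(s[:4]), int(s[4:6]), int(s[6:8])), "full"
        except ValueError:
            return None, "partial"  # malformed (e.g. month 13)
    return None, "partial"  # 4/6-digit partial or malformed


def compute_tto(r: AdverseEventReport,
                extraction_date: date = DEFAULT_EXTRACTION_DATE) -> TimeToOnsetRecord:
    event, ev_status = _parse_date(r.event_dt)
    start, st_status = _parse_date(r.start_dt)
    reason = "none"
    days: int | None = None
    if ev_status == "missing":
        reason = "missing_event"
    elif st_status == "missing":
        reason = "missing_start"
    elif ev_status == "partial" or st_status == "partial":
        reason = "partial_date"
    else:
        assert event is not None and start is not None
        delta = (event - start).days
        if delta < 0:
            reason = "negative_interval"
        elif not (_MIN_DATE <= start <= extraction_date and _MIN_DATE <= event <= extraction_date):
            reason = "out_of_range"
        else:
            days = delta
    return TimeToOnsetRecord(primaryid=r.primaryid, drug=r.target_drug,
                             sex=r.sex, tto_days=days, exclusion_reason=reason)


def compute_tto_records(reports: Iterable[AdverseEventReport],
                        extraction_date: date = DEFAULT_EXTRACTION_DATE,
                        ) -> list[TimeToOnsetRecord]:
    return [compute_tto(r, extraction_date) for r in reports]


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    return (float(np.percentile(arr, 25)), float(np.median(arr)),
            float(np.percentile(arr, 75)))


def tto_summary(records: Sequence[TimeToOnsetRecord],
                group_by: str = "drug") -> pd.DataFrame:
    """Per-group inclusion/exclusion tallies and median/quartiles.

    ``group_by`` is ``"drug"`` or ``"drug_sex"``.  The median of an even-sized
    sample is the midpoint of the two central order statistics, so half-day
    medians arise naturally.
    """
    if group_by not in ("drug", "drug_sex"):
        raise ValueError("group_by must be 'drug' or 'drug_sex'")

    def key(rec: TimeToOnsetRecord):
        if group_by == "drug":
            return (rec.drug or "unknown",)
        return (rec.drug or "unknown", rec.sex or "missing")

    groups: dict[tuple, list[TimeToOnsetRecord]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec)
    rows = []
    for k in sorted(groups):
        recs = groups[k]
        included = [r.tto_days for r in recs if r.included]
        row: dict[str, object] = {"drug": k[0]}
        if group_by == "drug_sex":
            row["sex"] = k[1]
        row["n_included"] = len(included)
        for reason in EXCLUSION_REASONS[1:]:
            row[f"n_{reason}"] = sum(1 for r in recs if r.exclusion_reason == reason)
        if included:
            q1, med, q3 = _quartiles(included)
            row.update(median=med, q1=q1, q3=q3)
        else:
            row.update(median=math.nan, q1=math.nan, q3=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _exact_rank_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by exhaustive enumeration over all
    group assignments, using midranks so ties are handled."""
    nx, ny = len(x), len(y)
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:nx])) - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    idx = range(nx + ny)
    for combo in itertools.combinations(idx, nx):
        u = float(sum(ranks[i] for i in combo)) - nx * (nx + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


def compare_tto(group_a: Sequence[float], group_b: Sequence[float],
                test: str = "mannwhitney") -> tuple[float, float, str]:
    """Compare two TTO samples; returns (statistic, p_value, test_name).

    The default is a two-sided Mann-Whitney rank-sum test: exact enumeration
    when both groups have n <= 8, normal approximation with tie correction
    otherwise.  ``test="logrank"`` runs an (uncensored) log-rank test instead.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "logrank":
        from lifelines.statistics import logrank_test

        res = logrank_test(group_a, group_b)
        return float(res.test_statistic), float(res.p_value), "log-rank"
    if test != "mannwhitney":
        raise ValueError(f"unknown test {test!r}")
    if len(group_a) <= 8 and len(group_b) <= 8:
        u, p = _exact_rank_test(group_a, group_b)
        return u, p, "mann-whitney-exact"
    u, p = stats.mannwhitneyu(group_a, group_b, alternative="two-sided",
                              method="asymptotic")
    return float(u), float(p), "mann-whitney-normal"
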