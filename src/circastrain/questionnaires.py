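"""Questionnaire-derived variables: MCTQ sleep timing and BDI scoring.

The Munich ChronoType Questionnaire (MCTQ) probes sleep onset/offset
separately for workdays and work-free days, plus time spent outdoors.
From it we derive midsleep on workdays (MSW), midsleep on free days
(MSF, a phase-of-entrainment marker) and social jetlag (SJL, the
absolute difference between the two midpoints, a circadian-strain
proxy).

The Beck Depression Inventory (BDI-I) is 21 items scored 0-3; a sum
above 10 marks clinically significant depressive symptoms.  A record
with exactly one missing item can still be categorized when the
partial sum already decides the category (partial sum <= 7 implies a
total below 8 even if the missing item were 3; partial sum >= 11
already exceeds the cut-off).

Clock times are accepted either as ``"HH:MM"`` strings or as decimal
hours in ``[0, 24)``; all returned times are decimal hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

ClockTime = Union[str, float, int]

BDI_N_ITEMS = 21
BDI_MAX_ITEM = 3

CATEGORY_LE = "<=10"
CATEGORY_GT = ">10"
CATEGORY_INDETERMINATE = "indeterminate"


def parse_clock(value: ClockTime) -> float:
    """Convert an ``"HH:MM"`` string or decimal hours to hours in [0, 24)."""
    if isinstance(value, str):
        parts = value.strip().split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"unparseable clock time: {value!r}")
        try:
            h = int(parts[0])
            m = int(parts[1])
            s = int(parts[2]) if len(parts) == 3 else 0
        except ValueError as exc:
            raise ValueError(f"unparseable clock time: {value!r}") from exc
        if not (0 <= m < 60 and 0 <= s < 60):
            raise ValueError(f"minutes/seconds out of range: {value!r}")
        hours = h + m / 60.0 + s / 3600.0
    else:
        hours = float(value)
    if not (0.0 <= hours < 24.0):
        raise ValueError(f"clock time must lie in [0, 24): got {hours}")
    return hours


def format_clock(hours: float) -> str:
    """Render decimal hours as ``HH:MM`` (minutes rounded)."""
    hours = hours % 24.0
    total_min = int(round(hours * 60))
    if total_min == 1440:
        total_min = 0
    return f"{total_min // 60:02d}:{total_min % 60:02d}"


def sleep_duration(onset: ClockTime, offset: ClockTime) -> float:
    """Sleep duration in hours, wrapping midnight when offset <= onset.

    Equal onset and offset is rejected: a zero-length sleep episode is
    indistinguishable from a 24 h one on a clock face.
    """
    o = parse_clock(onset)
    f = parse_clock(offset)
    duration = (f - o) % 24.0
    if duration == 0.0:
        raise ValueError("sleep onset equals offset: duration ambiguous (0 vs 24 h)")
    return duration


def midsleep(onset: ClockTime, duration: float) -> float:
    """Clock time (decimal hours) halfway through a sleep episode."""
    if not (0.0 < duration < 24.0):
        raise ValueError(f"duration must lie in (0, 24): got {duration}")
    return (parse_clock(onset) + duration / 2.0) % 24.0


def social_jetlag(msw: ClockTime, msf: ClockTime, signed: bool = False) -> float:
    """Social jetlag in hours: circular difference between the midsleeps.

    The default is the absolute shorter-arc difference, in [0, 12]
    (only nonnegative SJL values are analyzed downstream).  With
    ``signed=True`` the shorter-arc signed difference MSF - MSW in
    [-12, 12) is returned instead (positive = later on free days).
    """
    delta = (parse_clock(msf) - parse_clock(msw)) % 24.0
    if delta >= 12.0:
        delta -= 24.0
    return delta if signed else abs(delta)


def categorize_sjl(sjl: float, threshold: float = 1.0) -> bool:
    """True iff SJL strictly exceeds ``threshold`` hours (default 1 h)."""
    if sjl < 0:
        raise ValueError(f"SJL must be nonnegative: got {sjl}")
    return sjl > threshold


@dataclass
class MCTQRecord:
    """One subject's MCTQ answers (clock times as HH:MM or decimal hours)."""

    subject_id: str
    sleep_onset_w: ClockTime
    sleep_offset_w: ClockTime
    sleep_onset_f: ClockTime
    sleep_offset_f: ClockTime
    time_outdoors_w: Optional[float] = None
    time_outdoors_f: Optional[float] = None
    workdays_per_week: int = 5

    def __post_init__(self) -> None:
        for attr in ("sleep_onset_w", "sleep_offset_w", "sleep_onset_f", "sleep_offset_f"):
            parse_clock(getattr(self, attr))  # validate
        for attr in ("time_outdoors_w", "time_outdoors_f"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= float(v) <= 24.0):
                raise ValueError(f"{attr} must lie in [0, 24]: got {v}")
        if not (0 <= int(self.workdays_per_week) <= 7):
            raise ValueError("workdays_per_week must be 0-7")

    @property
    def sleep_duration_w(self) -> float:
        return sleep_duration(self.sleep_onset_w, self.sleep_offset_w)

    @property
    def sleep_duration_f(self) -> float:
        return sleep_duration(self.sleep_onset_f, self.sleep_offset_f)

    @property
    def msw(self) -> float:
        """Midsleep on workdays, decimal hours."""
        return midsleep(self.sleep_onset_w, self.sleep_duration_w)

    @property
    def msf(self) -> float:
        """Midsleep on work-free days (phase-of-entrainment marker)."""
        return midsleep(self.sleep_onset_f, self.sleep_duration_f)

    @property
    def sjl(self) -> float:
        return social_jetlag(self.msw, self.msf)


@dataclass
class BDIScore:
    """Outcome of scoring one BDI record."""

    total: Optional[int]
    category: str
    n_missing: int
    flag: Optional[str] = None


def score_bdi(items: Sequence[Optional[float]], cutoff: int = 10) -> BDIScore:
    """Score 21 BDI items, applying the single-missing-item rule.

    Complete records get a sum and the sum > cutoff category.  With
    exactly one missing item the sum is reported missing but the
    category is still resolved when the partial sum decides it either
    way; otherwise the record is indeterminate.  More than one missing
    item is always indeterminate (flag ``"too_many_missing"``).
    """
    if len(items) != BDI_N_ITEMS:
        raise ValueError(f"expected {BDI_N_ITEMS} BDI items, got {len(items)}")
    answered = []
    n_missing = 0
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_missing += 1
            continue
        iv = int(v)
        if iv != v or not (0 <= iv <= BDI_MAX_ITEM):
            raise ValueError(f"BDI item {i + 1} out of range {{0..3}}: {v!r}")
        answered.append(iv)

    partial = sum(answered)
    if n_missing == 0:
        category = CATEGORY_GT if partial > cutoff else CATEGORY_LE
        return BDIScore(total=partial, category=category, n_missing=0)
    if n_missing == 1:
        if partial > cutoff:
            return BDIScore(None, CATEGORY_GT, 1)
        if partial + BDI_MAX_ITEM <= cutoff:
            return BDIScore(None, CATEGORY_LE, 1)
        return BDIScore(None, CATEGORY_INDETERMINATE, 1, flag="unresolvable_missing")
    return BDIScore(None, CATEGORY_INDETERMINATE, n_missing, flag="too_many_missing")


@dataclass
class BDIRecord:
    """One subject's 21 BDI item responses (``None``/NaN = missing)."""

    subject_id: str
    items: Sequence[Optional[float]] = field(default_factory=list)

    def score(self, cutoff: int = 10) -> BDIScore:
        return score_bdi(self.items, cutoff=cutoff)


def _complete_cases(matrix: np.ndarray) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("item matrix must be 2-D (subjects x items)")
    return x[~np.isnan(x).any(axis=1)]


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha for internal consistency of a scale.

    alpha = k/(k-1) * (1 - sum of item variances / variance of sums),
    computed on complete cases with population (divide-by-n) variances.
    The value is invariant to the variance denominator as long as the
    same convention is used throughout; population is used here.
    """
    x = _complete_cases(item_matrix)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 2:
        raise ValueError("need at least 2 complete cases")
    item_vars = x.var(axis=0)
    total_var = x.sum(axis=1).var()
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return (k / (k - 1.0)) * (1.0 - item_vars.sum() / total_var)


def item_total_corrected(item_matrix) -> np.ndarray:
    """Corrected item-total correlations (item vs sum of the others).

    Items with zero variance (or when the rest-score is constant) get
    NaN rather than an arbitrary value.
    """
    x = _complete_cases(item_matrix)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    total = x.sum(axis=1)
    out = np.empty(k)
    for j in range(k):
        rest = total - x[:, j]
        if x[:, j].std() == 0 or rest.std() == 0:
            out[j] = np.nan
            continue
        out[j] = np.corrcoef(x[:, j], rest)[0, 1]
    return out
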