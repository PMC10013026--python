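"""Nonparametric and cosinor circadian metrics.

All operators take a :class:`~circastrain.actigraphy.DayWindow`
(a binned recording with its selected analysis days) and skip missing
bins.

* Inter-daily stability (IS) quantifies how consistently the 24-h
  profile repeats across days: the variance of the mean daily pattern
  relative to total variance, in [0, 1] (reported 0-100 scaled as
  well).
* Intra-daily variability (IV) quantifies rhythm fragmentation: the
  mean-square successive difference relative to the variance; about 2
  for uncorrelated noise, 4 for a strictly alternating series, near 0
  for a smooth rhythm.
* The cosinor fit is an ordinary least-squares fit of
  ``x(t) = M + b_c cos(2 pi t / 24) + b_s sin(2 pi t / 24)``; MESOR M
  is the fitted mean, amplitude the half peak-to-trough, acrophase the
  clock time of the fitted peak.

Both IS and IV operate on the 10-min bin basis of the preprocessed
recordings (144 bins/day), matching the binning of the study design
rather than hourly means; IV treats the multi-day window as one
continuous sequence (day boundaries are not breaks) and drops
difference pairs that span a missing bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .actigraphy import DayWindow

#: clock windows (start, end) in decimal hours; end <= start wraps midnight,
#: end may exceed 24 for readability (25 == 1:00 next day).
DEFAULT_WINDOWS = {
    "day": (7.0, 17.0),
    "morning": (8.0, 10.0),
    "afternoon": (13.0, 15.0),
    "night": (20.0, 25.0),
}

_IS_OVERSHOOT_TOL = 1e-9


def interdaily_stability(window: DayWindow) -> Tuple[float, float]:
    """IS of a windowed recording, returned as (raw in [0,1], 0-100 scaled).

    IS = [N * sum_b (xbar_b - xbar)^2] / [P * sum_i (x_i - xbar)^2]
    with P bins per day, xbar_b the across-day mean of bin-of-day b
    (missing bins skipped), xbar the grand mean and N the number of
    non-missing observations.

    On a fully observed window the ratio cannot exceed 1 and an
    overshoot beyond floating error raises.  With missing bins the
    unbalanced estimator can exceed 1 slightly (the bin means are no
    longer a projection of the data); such values are clamped to 1
    with a warning rather than rejected.
    """
    X = window.matrix()
    if X.shape[0] < 2:
        raise ValueError("IS needs at least 2 retained days")
    flat = X.ravel()
    finite = np.isfinite(flat)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("no observed bins")
    grand = flat[finite].mean()
    denom_ss = float(((flat[finite] - grand) ** 2).sum())
    if denom_ss == 0:
        raise ValueError("constant series: IS undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(X, axis=0)
    observed_cols = np.isfinite(col_means)
    P = X.shape[1]
    num = n * float(((col_means[observed_cols] - grand) ** 2).sum())
    is_raw = num / (P * denom_ss)
    if is_raw > 1.0 + _IS_OVERSHOOT_TOL:
        if n == X.size:
            raise ValueError(f"IS exceeded 1 ({is_raw}) on a fully observed "
                             "window; inconsistent input")
        warnings.warn(f"IS of {is_raw:.4f} from unbalanced missingness "
                      "clamped to 1")
    is_raw = min(max(is_raw, 0.0), 1.0)
    return is_raw, 100.0 * is_raw


def intradaily_variability(window: DayWindow) -> float:
    """IV of a windowed recording.

    IV = [N * sum of squared successive differences] /
         [(N - 1) * sum of squared deviations from the mean],
    with the successive-difference sum taken only over adjacent pairs
    of non-missing bins of the continuous multi-day series.
    """
    s = window.series()
    finite = np.isfinite(s)
    n = int(finite.sum())
    if n < 2:
        raise ValueError("IV needs at least 2 observed bins")
    pair = finite[1:] & finite[:-1]
    if not pair.any():
        raise ValueError("no adjacent pairs of observed bins")
    diffs = (s[1:] - s[:-1])[pair]
    mean = s[finite].mean()
    denom_ss = float(((s[finite] - mean) ** 2).sum())
    if denom_ss == 0:
        raise ValueError("constant series: IV undefined")
    return n * float((diffs ** 2).sum()) / ((n - 1) * denom_ss)


@dataclass
class CosinorFit:
    """Least-squares 24-h cosinor parameters for one subject/channel."""

    mesor: float
    amplitude: float
    acrophase_hours: float  # NaN when the amplitude is (numerically) zero
    period_hours: float
    n_obs: int

    @property
    def acrophase_defined(self) -> bool:
        return bool(np.isfinite(self.acrophase_hours))


def cosinor_fit(window: DayWindow, period_hours: float = 24.0) -> CosinorFit:
    """Fit ``M + A cos(2 pi (t - phi) / period)`` by least squares.

    ``t`` is the clock-anchored time of each non-missing bin start.
    Acrophase phi is returned in decimal hours in [0, period).  A
    constant input yields amplitude 0 with the acrophase flagged
    undefined (NaN); a rank-deficient design (all observations at a
    single clock time) raises.
    """
    rec = window.recording
    X = window.matrix()
    P = window.bins_per_day
    bin_hours = rec.epoch_minutes / 60.0
    # absolute hours from the first selected midnight, bin starts
    t = (np.arange(X.size) * bin_hours).reshape(X.shape)
    y = X.ravel()
    t = t.ravel()
    ok = np.isfinite(y)
    y, t = y[ok], t[ok]
    if len(y) < 3:
        raise ValueError("cosinor needs at least 3 observed bins")
    if np.ptp(y) == 0:
        return CosinorFit(mesor=float(y[0]), amplitude=0.0,
                          acrophase_hours=float("nan"),
                          period_hours=period_hours, n_obs=len(y))
    w = 2.0 * np.pi / period_hours
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient cosinor design "
                         "(all observations at too few distinct clock times)")
    mesor, bc, bs = (float(c) for c in coef)
    amplitude = float(np.hypot(bc, bs))
    scale = max(abs(mesor), float(np.abs(y).max()), 1.0)
    if amplitude <= 1e-12 * scale:
        return CosinorFit(mesor=mesor, amplitude=0.0, acrophase_hours=float("nan"),
                          period_hours=period_hours, n_obs=len(y))
    acro = (np.arctan2(bs, bc) * period_hours / (2.0 * np.pi)) % period_hours
    return CosinorFit(mesor=mesor, amplitude=amplitude, acrophase_hours=float(acro),
                      period_hours=period_hours, n_obs=len(y))


@dataclass
class DailyProfile:
    """Central 24-h profile: one value per bin-of-day starting 0:00.

    Bin b covers the half-open clock interval [b*w, (b+1)*w) minutes.
    Group profiles additionally carry per-bin quartiles.
    """

    label: str
    channel: str
    epoch_minutes: float
    values: np.ndarray
    q1: Optional[np.ndarray] = None
    q3: Optional[np.ndarray] = None
    n: int = 1

    @property
    def bin_start_hours(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.epoch_minutes / 60.0


def individual_profile(window: DayWindow, stat: str = "median") -> DailyProfile:
    """Per-subject daily profile: per bin-of-day median (or mean) across days.

    Even-count medians use the midpoint convention.  Bins never
    observed are NaN.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    X = window.matrix()
    func = np.nanmedian if stat == "median" else np.nanmean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = func(X, axis=0)
    rec = window.recording
    return DailyProfile(label=rec.subject_id, channel=rec.channel,
                        epoch_minutes=rec.epoch_minutes, values=values,
                        n=X.shape[0])


def group_profile(profiles: Sequence[DailyProfile], label: str = "group") -> DailyProfile:
    """Group profile: per-bin median and interquartile range across subjects."""
    if not profiles:
        raise ValueError("need at least one profile")
    P = len(profiles[0].values)
    for p in profiles:
        if len(p.values) != P:
            raise ValueError("profiles have mismatched bin counts")
    stack = np.vstack([p.values for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
        q1 = np.nanpercentile(stack, 25, axis=0)
        q3 = np.nanpercentile(stack, 75, axis=0)
    return DailyProfile(label=label, channel=profiles[0].channel,
                        epoch_minutes=profiles[0].epoch_minutes,
                        values=med, q1=q1, q3=q3, n=len(profiles))


def window_median(window: DayWindow, clock_window: Tuple[float, float]) -> float:
    """Median over all non-missing bins whose start falls in a clock window.

    The window is a half-open clock interval [start, end); ``end <=
    start`` (or end > 24) wraps past midnight, e.g. (20, 25) covers
    20:00 to 1:00.  Pools bins across all selected days.  Returns NaN
    with a warning when the window holds no observed bin.
    """
    start, end = clock_window
    start %= 24.0
    span = (end - start) % 24.0
    if span == 0:
        span = 24.0
    bin_hours = window.recording.epoch_minutes / 60.0
    clock = (np.arange(window.bins_per_day) * bin_hours) % 24.0
    sel = ((clock - start) % 24.0) < span
    X = window.matrix()[:, sel]
    vals = X[np.isfinite(X)]
    if vals.size == 0:
        warnings.warn(f"no observed bins in clock window {clock_window}; returning NaN")
        return float("nan")
    return float(np.median(vals))


def zeitgeber_strength(light_window: DayWindow,
                       morning: Tuple[float, float] = (8.0, 10.0),
                       evening: Tuple[float, float] = (20.0, 25.0)) -> float:
    """Ratio of morning to evening median light exposure.

    A proxy for the strength of the light-dark cycle as a zeitgeber:
    high morning light against dim evenings makes a strong
    synchronizer.  Undefined (NaN, with a warning) when the evening
    median is zero or missing -- never reported as infinity.
    """
    m = window_median(light_window, morning)
    e = window_median(light_window, evening)
    if not np.isfinite(e) or e == 0:
        warnings.warn("evening light median is zero or missing; "
                      "zeitgeber strength undefined")
        return float("nan")
    if not np.isfinite(m):
        return float("nan")
    return m / e


@dataclass
class CircadianMetrics:
    """Tidy per-subject x channel metric bundle."""

    subject_id: str
    channel: str
    n_days_used: int
    is_raw: float = float("nan")
    is_scaled: float = float("nan")
    iv: float = float("nan")
    mesor: float = float("nan")
    amplitude: float = float("nan")
    acrophase: float = float("nan")

    def rows(self) -> List[dict]:
        return [
            dict(subject_id=self.subject_id, channel=self.channel,
                 metric=name, value=getattr(self, name),
                 n_days_used=self.n_days_used)
            for name in ("is_raw", "is_scaled", "iv", "mesor", "amplitude", "acrophase")
        ]


def compute_metrics(window: DayWindow) -> CircadianMetrics:
    """IS, IV and cosinor parameters for one windowed channel recording."""
    rec = window.recording
    out = CircadianMetrics(subject_id=rec.subject_id, channel=rec.channel,
                           n_days_used=len(window.days))
    out.is_raw, out.is_scaled = interdaily_stability(window)
    out.iv = intradaily_variability(window)
    fit = cosinor_fit(window)
    out.mesor, out.amplitude, out.acrophase = fit.mesor, fit.amplitude, fit.acrophase_hours
    return out
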