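"""Actimetry parsing, harmonization, binning and quality control.

Wrist actimeters record locomotor activity (counts), ambient light
(lux) and, on some devices, skin temperature (deg C) at a fixed native
epoch.  Two CSV dialects are supported, mirroring the two device
families used in the field:

* dialect ``"A"`` (Actiwatch-2-like): comma separated, columns
  ``timestamp,activity,light`` with ISO timestamps; no temperature
  channel.
* dialect ``"B"`` (ActTrust-like): semicolon separated, columns
  ``DATE/TIME;ACTIVITY;LIGHT;TEMPERATURE`` with ``dd/mm/yyyy
  HH:MM:SS`` timestamps.

Preprocessing follows the standard rules for this kind of study:
series are binned to 10-min epochs (activity summed, light and
temperature averaged), off-wrist periods are detected as runs of at
least 10 consecutive zero 10-min activity bins and masked across all
channels, days with more than 4 h of missing data are excluded, and
analysis windows of 7 or 14 consecutive retained days (hence covering
every weekday) are selected.  Light from brand B is rescaled onto the
brand-A lux scale by a through-origin regression slope obtained from a
simultaneous dual-device wear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

CHANNELS = ("activity", "light", "temperature")

#: default per-channel aggregation when rebinning
AGGREGATION = {"activity": "sum", "light": "mean", "temperature": "mean"}

MINUTES_PER_DAY = 1440


@dataclass
class ActimetryRecording:
    """One subject x one channel gapless time series.

    Gaps are represented as missing bins, never as absent rows.
    Missing values are stored as NaN *and* flagged in ``missing`` so
    downstream operators behave identically whichever encoding a
    caller inspects.
    """

    subject_id: str
    device_brand: str
    channel: str
    start: datetime
    epoch_minutes: float
    values: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.missing is None:
            self.missing = np.isnan(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool).copy()
        if len(self.values) != len(self.missing):
            raise ValueError("values and missing mask must have equal length")
        self.missing |= np.isnan(self.values)
        self.values[self.missing] = np.nan
        if self.epoch_minutes <= 0:
            raise ValueError("epoch_minutes must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n(self) -> int:
        return len(self.values)

    def timestamps(self) -> List[datetime]:
        step = timedelta(minutes=self.epoch_minutes)
        return [self.start + i * step for i in range(self.n)]

    def clock_hours(self) -> np.ndarray:
        """Clock time (decimal hours of day) of each epoch start."""
        start_h = self.start.hour + self.start.minute / 60 + self.start.second / 3600
        return (start_h + np.arange(self.n) * self.epoch_minutes / 60.0) % 24.0

    def with_values(self, values: np.ndarray, missing: Optional[np.ndarray] = None) -> "ActimetryRecording":
        return replace(self, values=values, missing=missing)


# ---------------------------------------------------------------------------
# CSV dialects

_DIALECTS = {
    "A": dict(sep=",", ts_fmt="%Y-%m-%d %H:%M:%S",
              header=["timestamp", "activity", "light"],
              channels=("activity", "light")),
    "B": dict(sep=";", ts_fmt="%d/%m/%Y %H:%M:%S",
              header=["DATE/TIME", "ACTIVITY", "LIGHT", "TEMPERATURE"],
              channels=("activity", "light", "temperature")),
}


def dialect_channels(dialect: str) -> Tuple[str, ...]:
    """Channels a device dialect records (temperature only on brand B)."""
    return _DIALECTS[_check_dialect(dialect)]["channels"]


def _check_dialect(dialect: str) -> str:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    return dialect


def write_recording(path, recordings: Dict[str, ActimetryRecording], dialect: str) -> None:
    """Serialize channel recordings of one subject to a device-dialect CSV."""
    spec = _DIALECTS[_check_dialect(dialect)]
    chans = [c for c in spec["channels"] if c in recordings]
    if not chans:
        raise ValueError("no writable channels for this dialect")
    ref = recordings[chans[0]]
    for c in chans[1:]:
        r = recordings[c]
        if r.start != ref.start or r.n != ref.n or r.epoch_minutes != ref.epoch_minutes:
            raise ValueError("channel recordings are not aligned")
    sep = spec["sep"]
    step = timedelta(minutes=ref.epoch_minutes)
    with open(path, "w", newline="") as fh:
        fh.write(sep.join(spec["header"][: len(chans) + 1]) + "\n")
        for i in range(ref.n):
            ts = (ref.start + i * step).strftime(spec["ts_fmt"])
            cells = [ts]
            for c in chans:
                v = recordings[c].values[i]
                cells.append("" if np.isnan(v) else format(v, "g"))
            fh.write(sep.join(cells) + "\n")


def parse_recording(path, dialect: str, subject_id: Optional[str] = None,
                    device_brand: Optional[str] = None) -> Dict[str, ActimetryRecording]:
    """Parse a device CSV into per-channel recordings.

    Timestamp gaps that are whole multiples of the native epoch are
    materialized as missing bins; malformed rows and non-monotone
    timestamps raise with the offending line number.
    """
    spec = _DIALECTS[_check_dialect(dialect)]
    sep, fmt = spec["sep"], spec["ts_fmt"]
    if device_brand is None:
        device_brand = dialect
    if subject_id is None:
        import os
        subject_id = os.path.splitext(os.path.basename(str(path)))[0]

    times: List[datetime] = []
    rows: List[List[float]] = []
    n_chan = None
    with open(path) as fh:
        header = fh.readline()
        n_chan = len(header.rstrip("\n").split(sep)) - 1
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(sep)
            if len(cells) != n_chan + 1:
                raise ValueError(f"{path}: line {lineno}: expected {n_chan + 1} fields, got {len(cells)}")
            try:
                ts = datetime.strptime(cells[0], fmt)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad timestamp {cells[0]!r}") from exc
            vals = []
            for cell in cells[1:]:
                cell = cell.strip()
                if cell == "" or cell.upper() == "NAN":
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError as exc:
                        raise ValueError(f"{path}: line {lineno}: bad value {cell!r}") from exc
            if times and ts <= times[-1]:
                raise ValueError(f"{path}: line {lineno}: non-monotone timestamp {cells[0]!r}")
            times.append(ts)
            rows.append(vals)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least two rows to infer the epoch")

    epoch = (times[1] - times[0]).total_seconds() / 60.0
    # materialize gaps as missing bins
    filled: List[List[float]] = []
    expected = times[0]
    step = timedelta(minutes=epoch)
    for idx, (ts, vals) in enumerate(zip(times, rows)):
        if ts != expected:
            gap_min = (ts - expected).total_seconds() / 60.0
            n_gap = gap_min / epoch
            if n_gap < 0 or abs(n_gap - round(n_gap)) > 1e-9:
                raise ValueError(
                    f"{path}: timestamp {ts} is not aligned to the {epoch:g}-min epoch grid")
            filled.extend([[np.nan] * n_chan] * int(round(n_gap)))
        filled.append(vals)
        expected = ts + step

    arr = np.asarray(filled, dtype=float)
    chans = spec["channels"][:n_chan]
    out = {}
    for j, chan in enumerate(chans):
        out[chan] = ActimetryRecording(
            subject_id=subject_id, device_brand=device_brand, channel=chan,
            start=times[0], epoch_minutes=epoch, values=arr[:, j])
    return out


# ---------------------------------------------------------------------------
# Binning

def bin_series(rec: ActimetryRecording, target_minutes: float = 10.0,
               how: Optional[str] = None) -> ActimetryRecording:
    """Aggregate a recording to ``target_minutes`` bins.

    Activity is summed; light and temperature are averaged (standard
    actigraphy practice; override with ``how``).  A binned value is
    missing iff *all* native epochs in the bin are missing; partially
    observed bins aggregate the observed epochs only.
    """
    ratio = target_minutes / rec.epoch_minutes
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"target width {target_minutes} min is not an integer multiple of "
            f"the native {rec.epoch_minutes} min epoch")
    ratio = int(round(ratio))
    if how is None:
        how = AGGREGATION[rec.channel]
    if how not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {how!r}")
    if ratio == 1:
        return rec.with_values(rec.values.copy(), rec.missing.copy())

    n_full = -(-rec.n // ratio) * ratio  # pad tail to whole bins
    padded = np.full(n_full, np.nan)
    padded[: rec.n] = rec.values
    mat = padded.reshape(-1, ratio)
    all_missing = np.isnan(mat).all(axis=1)
    with np.errstate(invalid="ignore"):
        if how == "sum":
            agg = np.nansum(mat, axis=1)
        else:
            agg = np.full(len(mat), np.nan)
            ok = ~all_missing
            agg[ok] = np.nanmean(mat[ok], axis=1)
    agg[all_missing] = np.nan
    return replace(rec, epoch_minutes=float(target_minutes), values=agg,
                   missing=all_missing)


# ---------------------------------------------------------------------------
# Off-wrist detection

@dataclass
class OffwristResult:
    """Mask of off-wrist bins plus the flagged runs for review."""

    mask: np.ndarray
    runs: List[Tuple[int, int]]  # (start index, length) of each flagged run


def detect_offwrist(activity: ActimetryRecording, min_run: int = 10) -> OffwristResult:
    """Flag maximal runs of >= ``min_run`` consecutive zero activity bins.

    Operates on the (10-min binned) activity channel; the resulting
    mask is meant to be propagated to all channels of the subject via
    :func:`apply_offwrist`.  Runs shorter than ``min_run`` are left
    untouched.  The flagged runs are returned for review, replacing
    the manual visual confirmation step with an auditable list.
    """
    zero = (activity.values == 0) & ~activity.missing
    mask = np.zeros(activity.n, dtype=bool)
    runs: List[Tuple[int, int]] = []
    i = 0
    n = activity.n
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i >= min_run:
                mask[i:j] = True
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return OffwristResult(mask=mask, runs=runs)


def apply_offwrist(recordings: Iterable[ActimetryRecording],
                   mask: np.ndarray) -> List[ActimetryRecording]:
    """Mark masked bins missing on every channel (monotone: never unmasks)."""
    out = []
    for rec in recordings:
        if len(mask) != rec.n:
            raise ValueError("mask length does not match recording")
        values = rec.values.copy()
        values[mask] = np.nan
        out.append(rec.with_values(values, rec.missing | mask))
    return out


# ---------------------------------------------------------------------------
# Day exclusion and window selection

@dataclass
class DayWindow:
    """Retained calendar days of one binned recording.

    ``days`` holds the retained (or, after :func:`select_window`,
    selected) calendar days; ``missing_per_day`` counts missing bins
    for every *complete* calendar day in the recording.  Analysis days
    run midnight-to-midnight in local time.
    """

    recording: ActimetryRecording
    days: List[date]
    missing_per_day: Dict[date, int]
    start_index: int  # index of the first midnight bin
    eligible: bool = True
    status: str = "ok"

    @property
    def bins_per_day(self) -> int:
        return int(round(MINUTES_PER_DAY / self.recording.epoch_minutes))

    @property
    def first_day(self) -> Optional[date]:
        return min(self.missing_per_day) if self.missing_per_day else None

    def day_slice(self, d: date) -> slice:
        offset = (d - self.first_day).days
        i0 = self.start_index + offset * self.bins_per_day
        return slice(i0, i0 + self.bins_per_day)

    def matrix(self, days: Optional[Sequence[date]] = None) -> np.ndarray:
        """(n_days, bins_per_day) array of values, NaN where missing."""
        days = list(self.days if days is None else days)
        P = self.bins_per_day
        out = np.full((len(days), P), np.nan)
        for r, d in enumerate(days):
            out[r] = self.recording.values[self.day_slice(d)]
        return out

    def series(self) -> np.ndarray:
        """Selected days flattened in calendar order (one continuous series)."""
        return self.matrix().ravel()


def exclude_days(rec: ActimetryRecording, max_missing_hours: float = 4.0) -> DayWindow:
    """Retain calendar days with at most ``max_missing_hours`` missing.

    The rule is strict: a day is excluded only when missing time
    *exceeds* the threshold (at 10-min bins, 24 missing bins retain
    the day, 25 exclude it).  Partial first/last days are not
    considered.  An empty result is returned with a diagnostic status
    rather than raised.
    """
    P = MINUTES_PER_DAY / rec.epoch_minutes
    if abs(P - round(P)) > 1e-9:
        raise ValueError("epoch width must divide 1440 minutes")
    P = int(round(P))
    threshold = max_missing_hours * 60.0 / rec.epoch_minutes

    # advance to the first midnight
    start_h = rec.start.hour + rec.start.minute / 60 + rec.start.second / 3600
    if start_h == 0:
        start_index = 0
        first_day = rec.start.date()
    else:
        start_index = int(round((24.0 - start_h) * 60.0 / rec.epoch_minutes))
        first_day = rec.start.date() + timedelta(days=1)

    n_days = (rec.n - start_index) // P
    missing_per_day: Dict[date, int] = {}
    retained: List[date] = []
    for k in range(n_days):
        d = first_day + timedelta(days=k)
        sl = slice(start_index + k * P, start_index + (k + 1) * P)
        miss = int(rec.missing[sl].sum())
        missing_per_day[d] = miss
        if miss <= threshold:
            retained.append(d)
    status = "ok" if retained else "no retainable day (all days exceed the missing-data limit)"
    return DayWindow(recording=rec, days=retained, missing_per_day=missing_per_day,
                     start_index=start_index, eligible=bool(retained), status=status)


def select_window(window: DayWindow, n_days: int = 7) -> DayWindow:
    """Earliest block of ``n_days`` consecutive retained calendar days.

    Any block of >= 7 consecutive calendar days necessarily contains
    every weekday, satisfying the one-of-each-weekday inclusion rule.
    Subjects without such a block are returned with ``eligible=False``
    and an explicit status, never silently dropped.
    """
    if n_days < 7:
        raise ValueError("analysis windows are 7 or 14 days (>= 7 required)")
    retained = sorted(window.days)
    run: List[date] = []
    for d in retained:
        if run and (d - run[-1]).days == 1:
            run.append(d)
        else:
            run = [d]
        if len(run) == n_days:
            selected = run
            weekdays = {x.weekday() for x in selected}
            assert weekdays == set(range(7))
            return replace(window, days=selected, eligible=True,
                           status=f"selected {n_days} consecutive retained days")
    return replace(window, days=[], eligible=False,
                   status=f"ineligible: no block of {n_days} consecutive retained days "
                          f"({len(retained)} days retained)")


# ---------------------------------------------------------------------------
# Cross-device harmonization

def fit_cross_device_slope(paired_light_a, paired_light_b, min_pairs: int = 100,
                           intercept: bool = False):
    """Regression slope of brand-B light on brand-A light.

    Fitted through the origin (least squares, slope = sum(ab)/sum(a^2))
    from a simultaneous dual-device wear; brand A is the reference lux
    scale.  ``intercept=True`` returns ``(slope, intercept)`` from an
    ordinary least-squares fit instead.
    """
    a = np.asarray(paired_light_a, dtype=float)
    b = np.asarray(paired_light_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired non-missing bins, got {len(a)}")
    if intercept:
        X = np.column_stack([a, np.ones_like(a)])
        coef, *_ = np.linalg.lstsq(X, b, rcond=None)
        return float(coef[0]), float(coef[1])
    denom = float(np.sum(a * a))
    if denom == 0:
        raise ValueError("reference series is identically zero")
    return float(np.sum(a * b) / denom)


def normalize_light(rec: ActimetryRecording, slope: float) -> ActimetryRecording:
    """Rescale brand-B light onto the brand-A scale (divide by slope)."""
    if not np.isfinite(slope) or slope <= 0:
        raise ValueError(f"slope must be a positive finite number: got {slope}")
    if rec.channel != "light":
        raise ValueError("normalize_light expects the light channel")
    if rec.device_brand != "B":
        return rec.with_values(rec.values.copy(), rec.missing.copy())
    return rec.with_values(rec.values / slope, rec.missing.copy())


def normalize_activity(rec: ActimetryRecording, scale: float = 1.0,
                       offset: float = 0.0) -> ActimetryRecording:
    """Affine harmonization of brand-B activity counts.

    The exact manufacturer transform is configuration, not code: pass
    the (scale, offset) recommended for the device pair in use.  Brand
    A is returned unchanged.
    """
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"scale must be a positive finite number: got {scale}")
    if rec.channel != "activity":
        raise ValueError("normalize_activity expects the activity channel")
    if rec.device_brand != "B":
        return rec.with_values(rec.values.copy(), rec.missing.copy())
    return rec.with_values(rec.values * scale + offset, rec.missing.copy())
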