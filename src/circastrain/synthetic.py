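"""Synthetic cohorts and actimetry with the structure the analysis assumes.

No individual-level data from the original field study are available,
so every downstream stage is exercised on simulated subjects whose
marginals and effect structure mirror the study conditions: ~22%
prevalence of clinically significant depressive symptoms (BDI > 10) at
reference covariates, a near-zero-inflated social-jetlag distribution
(quartiles starting at 0), 56% women, ages 16-92, and a log-linear
dependence of the BDI > 10 probability on the SJL > 1 h indicator
(prevalence ratio 2.19) and on morning light per 500 lx (prevalence
ratio 0.48).

Actimetry is generated at the device-native epoch for three channels:

* light -- a daylight envelope gated by photoperiod (simple cosine
  day-length model at the configured latitude, ~29 deg S by default;
  no ephemeris), scaled per subject so the 8:00-10:00 median tracks
  the subject's latent morning light, over a dim indoor/evening
  baseline; brand-B devices read ``light_slope_b`` times higher than
  brand A, exercising the cross-device normalization.
* activity -- a smooth unimodal daytime template (half-cosine bump
  peaking early afternoon) over a positive wake baseline, near zero
  during the sleep window implied by the subject's reported sleep
  times, with seeded Poisson noise.
* skin temperature -- a 24-h cosine in antiphase to activity
  (distal skin temperature rises during rest).

Off-wrist episodes are injected as runs of zeros across all channels
(length 10-30 ten-minute bins, placed in waking hours), matching the
downstream detection rule.  All randomness flows from
``numpy.random.default_rng([seed, subject_index, stream])``, so a
cohort is bit-identical for a given spec and any subject can be
regenerated in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .actigraphy import ActimetryRecording, write_recording
from .questionnaires import BDIRecord, MCTQRecord, score_bdi, social_jetlag, CATEGORY_GT

SEASON_MAR_SEP = "Mar20-Sep22"
SEASON_SEP_MAR = "Sep22-Mar20"

_OBLIQUITY_RAD = math.radians(23.44)


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    The defaults are the calibration of the emulated study: 22%
    baseline prevalence of BDI > 10, prevalence ratios 2.19 (SJL > 1 h)
    and 0.48 (per 500 lx of morning light), 56% women, ages 16-92,
    ~half of recordings in the March-September season, 14-day
    recordings at ~29 deg S.
    """

    n_subjects: int = 210
    seed: int = 0
    prevalence_base: float = 0.22
    pr_sjl: float = 2.19
    pr_light_500lx: float = 0.48
    sex_ratio: float = 0.56
    age_range: Tuple[int, int] = (16, 92)
    season_mix: float = 0.5
    device_mix: float = 0.47
    light_slope_b: float = 1.5
    n_days: int = 14
    offwrist_rate: float = 0.1
    # environment / device plumbing
    latitude: float = -29.0
    native_epoch_minutes: float = 5.0
    activity_peak_hour: float = 14.0
    indoor_baseline_lux: float = 50.0
    evening_baseline_lux: float = 2.0
    morning_light_median: float = 400.0
    morning_light_sigma: float = 0.75
    sjl_zero_mass: float = 0.30
    sjl_mean_hours: float = 0.75
    strict: bool = False
    realistic_bdi_items: bool = False

    def validate(self) -> None:
        for name in ("prevalence_base", "sex_ratio", "season_mix", "device_mix",
                     "sjl_zero_mass"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]: got {v}")
        for name in ("pr_sjl", "pr_light_500lx", "light_slope_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_days < 14:
            raise ValueError("n_days must be >= 14 (the longest analysis window)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        if 1440.0 % self.native_epoch_minutes != 0:
            raise ValueError("native epoch must divide 1440 minutes")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        return cls(**d)


@dataclass
class SubjectRecord:
    """Covariates and latent traits of one simulated subject."""

    subject_id: str
    index: int
    age: int
    sex: str  # "female" | "male"
    season: str  # SEASON_MAR_SEP | SEASON_SEP_MAR
    device_brand: str  # "A" | "B"
    latent_morning_light: float  # lux, brand-A scale
    latent_sjl: float  # hours, >= 0


@dataclass
class Cohort:
    """A generated cohort: subjects with their MCTQ and BDI records."""

    spec: CohortSpec
    subjects: List[SubjectRecord]
    mctq: List[MCTQRecord]
    bdi: List[BDIRecord]

    def to_frame(self, bdi_cutoff: int = 10, sjl_threshold: float = 1.0) -> pd.DataFrame:
        """Analysis table with questionnaire-derived columns."""
        rows = []
        for s, m, b in zip(self.subjects, self.mctq, self.bdi):
            score = score_bdi(b.items, cutoff=bdi_cutoff)
            rows.append(dict(
                subject_id=s.subject_id, age=s.age, sex=s.sex,
                female=1.0 if s.sex == "female" else 0.0,
                season=s.season,
                season_mar_sep=1.0 if s.season == SEASON_MAR_SEP else 0.0,
                device_brand=s.device_brand,
                latent_morning_light=s.latent_morning_light,
                morning_light_500=s.latent_morning_light / 500.0,
                msw=m.msw, msf=m.msf, sjl=m.sjl,
                sjl_gt_1h=1.0 if m.sjl > sjl_threshold else 0.0,
                sleep_duration_w=m.sleep_duration_w,
                sleep_duration_f=m.sleep_duration_f,
                time_outdoors_w=m.time_outdoors_w,
                time_outdoors_f=m.time_outdoors_f,
                bdi_sum=score.total if score.total is not None else np.nan,
                bdi_category=score.category,
                bdi_gt10=1.0 if score.category == CATEGORY_GT else 0.0,
            ))
        return pd.DataFrame(rows)

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "cohort.csv", index=False)
        self.spec.to_json(directory / "cohort_spec.json")
        return directory / "cohort.csv"


def _quantize(hours: float, step_min: float = 15.0) -> float:
    """Quantize a clock time to the questionnaire reporting grid."""
    step = step_min / 60.0
    return (round(hours / step) * step) % 24.0


def day_length_hours(day_of_year: int, latitude: float) -> float:
    """Photoperiod from a simple cosine model (no ephemeris).

    Amplitude follows (24/pi) asin(tan|lat| tan(obliquity)); the phase
    puts the longest day at the winter/summer solstice appropriate for
    the hemisphere.
    """
    amp = (24.0 / math.pi) * math.asin(
        min(1.0, math.tan(math.radians(abs(latitude))) * math.tan(_OBLIQUITY_RAD)))
    # doy 172 ~ June solstice: northern longest day, southern shortest
    phase = math.cos(2.0 * math.pi * (day_of_year - 172) / 365.25)
    if latitude < 0:
        phase = -phase
    return 12.0 + amp * phase


def _subject_rng(spec: CohortSpec, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(spec.seed)) % (2 ** 31), int(index), int(stream)])


def _allocate_bdi_items(rng: np.random.Generator, total: int,
                        weights: Optional[np.ndarray]) -> List[int]:
    """Distribute a target sum over 21 items, each capped at 3."""
    items = np.zeros(21, dtype=int)
    if weights is None:
        weights = np.ones(21)
    for _ in range(total):
        open_idx = np.flatnonzero(items < 3)
        w = weights[open_idx]
        items[int(rng.choice(open_idx, p=w / w.sum()))] += 1
    return items.tolist()


#: mild item-level realism: lower endorsement of suicidal thoughts (item 9)
#: and weight loss (item 19), higher of the mood/self-evaluation items.
_REALISTIC_ITEM_WEIGHTS = np.array(
    [1.5, 1.3, 1.0, 1.2, 1.3, 1.0, 1.3, 1.3, 0.2, 0.8, 1.0, 1.0, 1.0, 0.9,
     1.1, 1.2, 1.2, 1.1, 0.3, 0.9, 1.2])


def generate_subject(spec: CohortSpec, index: int) -> Tuple[SubjectRecord, MCTQRecord, BDIRecord]:
    """Generate one subject (covariates, MCTQ answers, BDI items)."""
    rng = _subject_rng(spec, index, 0)
    sid = f"S{index:04d}"
    sex = "female" if rng.random() < spec.sex_ratio else "male"
    age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
    season = SEASON_MAR_SEP if rng.random() < spec.season_mix else SEASON_SEP_MAR
    brand = "B" if rng.random() < spec.device_mix else "A"
    morning_light = float(np.exp(rng.normal(np.log(spec.morning_light_median),
                                            spec.morning_light_sigma)))
    latent_sjl = 0.0 if rng.random() < spec.sjl_zero_mass else float(
        rng.exponential(spec.sjl_mean_hours))
    latent_sjl = min(latent_sjl, 6.0)

    # sleep timing: workday midsleep around 2:30, free days delayed by SJL
    msw = rng.normal(2.5, 0.7)
    dur_w = float(np.clip(rng.normal(7.7, 0.9), 4.5, 11.5))
    dur_f = float(np.clip(dur_w + rng.normal(0.5, 0.6), 4.5, 12.5))
    msf = msw + latent_sjl
    onset_w = _quantize(msw - dur_w / 2.0)
    offset_w = _quantize(msw + dur_w / 2.0)
    onset_f = _quantize(msf - dur_f / 2.0)
    offset_f = _quantize(msf + dur_f / 2.0)
    outdoors_w = float(np.clip(rng.gamma(2.0, 3.5), 0.0, 16.0))
    outdoors_f = float(np.clip(rng.gamma(2.0, 2.7), 0.0, 16.0))
    mctq = MCTQRecord(subject_id=sid, sleep_onset_w=onset_w, sleep_offset_w=offset_w,
                      sleep_onset_f=onset_f, sleep_offset_f=offset_f,
                      time_outdoors_w=round(outdoors_w * 2) / 2,
                      time_outdoors_f=round(outdoors_f * 2) / 2,
                      workdays_per_week=int(rng.choice([5, 6])))

    subject = SubjectRecord(subject_id=sid, index=index, age=age, sex=sex,
                            season=season, device_brand=brand,
                            latent_morning_light=morning_light,
                            latent_sjl=latent_sjl)

    # BDI category from the log-linear prevalence model, using the
    # *realized* (quantized) SJL so the fitted indicator matches.
    sjl_realized = mctq.sjl
    p = (spec.prevalence_base
         * spec.pr_sjl ** (1.0 if sjl_realized > 1.0 else 0.0)
         * spec.pr_light_500lx ** (morning_light / 500.0))
    if p > 1.0:
        if spec.strict:
            raise ValueError(
                f"model probability {p:.3f} > 1 for subject {sid} "
                f"(SJL {sjl_realized:.2f} h, morning light {morning_light:.0f} lx); "
                "rescale prevalence_base or the prevalence ratios")
        p = 1.0
    positive = rng.random() < p
    if positive:
        total = 11 + int(min(rng.poisson(4.0), 52))
    else:
        total = int(rng.binomial(10, 0.42))
    weights = _REALISTIC_ITEM_WEIGHTS if spec.realistic_bdi_items else None
    bdi = BDIRecord(subject_id=sid, items=_allocate_bdi_items(rng, total, weights))
    return subject, mctq, bdi


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort; bit-identical for identical (spec, seed)."""
    spec.validate()
    subjects, mctqs, bdis = [], [], []
    for i in range(spec.n_subjects):
        s, m, b = generate_subject(spec, i)
        subjects.append(s)
        mctqs.append(m)
        bdis.append(b)
    return Cohort(spec=spec, subjects=subjects, mctq=mctqs, bdi=bdis)


def _recording_start(spec: CohortSpec, subject: SubjectRecord,
                     rng: np.random.Generator) -> datetime:
    if subject.season == SEASON_MAR_SEP:
        base = date(2015, 4, 15)
        jitter = int(rng.integers(0, 120))  # mid-Apr .. mid-Aug
    else:
        base = date(2015, 10, 15)
        jitter = int(rng.integers(0, 120))  # mid-Oct .. mid-Feb
    return datetime.combine(base + timedelta(days=jitter), datetime.min.time())


def generate_actimetry(subject: SubjectRecord, spec: CohortSpec,
                       mctq: Optional[MCTQRecord] = None,
                       n_days: Optional[int] = None,
                       noise: bool = True) -> Dict[str, ActimetryRecording]:
    """Three-channel recording (activity, light, temperature) for a subject.

    The sleep window comes from the subject's reported workday sleep
    times (regenerated deterministically when ``mctq`` is omitted).
    With ``noise=False`` the deterministic templates are returned,
    which makes construction-level guarantees exact (e.g. brand-B
    light is exactly ``light_slope_b`` times the same-seed brand-A
    recording; the activity acrophase equals the configured template
    peak).
    """
    spec.validate()
    n_days = int(n_days if n_days is not None else spec.n_days)
    if n_days < 7:
        raise ValueError("recordings must span at least 7 days")
    if mctq is None:
        _, mctq, _ = generate_subject(spec, subject.index)
    rng = _subject_rng(spec, subject.index, 1)

    epoch = spec.native_epoch_minutes
    per_day = int(round(1440.0 / epoch))
    n = n_days * per_day
    start = _recording_start(spec, subject, rng)
    t_clock = (np.arange(n) * epoch / 60.0) % 24.0
    day_idx = np.arange(n) // per_day
    doy = np.array([(start.date() + timedelta(days=int(k))).timetuple().tm_yday
                    for k in range(n_days)])

    # --- sleep window from reported workday sleep times
    dur = mctq.sleep_duration_w
    onset = (mctq.msw - dur / 2.0) % 24.0
    asleep = ((t_clock - onset) % 24.0) < dur

    # --- activity: positive wake baseline + half-cosine daytime bump
    peak = spec.activity_peak_hour + float(rng.normal(0.0, 0.75))
    bump_width = 10.0  # hours of support, peak +/- 5 h
    phase = (t_clock - peak + 12.0) % 24.0 - 12.0  # circular offset from peak
    bump = np.where(np.abs(phase) < bump_width / 2.0,
                    np.cos(np.pi * phase / bump_width), 0.0)
    amp = 250.0 * float(np.exp(rng.normal(0.0, 0.3)))
    base = 20.0
    activity = np.where(asleep, 0.0, base + amp * bump)
    if noise:
        # bursty wake counts: multiplicative lognormal with a
        # subject-specific magnitude, so fragmentation (IV) and
        # stability (IS) genuinely differ between subjects
        burst_sigma = float(rng.uniform(0.3, 0.8))
        activity = activity * np.where(asleep, 1.0, np.exp(rng.normal(0.0, burst_sigma, n)))
        activity = activity + np.where(asleep, rng.poisson(1.0, n), rng.poisson(5.0, n))
    activity = activity.astype(float)

    # --- light: photoperiod-gated daylight envelope + dim baseline
    D = np.array([day_length_hours(int(d), spec.latitude) for d in doy])[day_idx]
    sunrise = 12.0 - D / 2.0
    frac = (t_clock - sunrise) / D
    daylight = (frac > 0) & (frac < 1)
    env = np.where(daylight, np.sin(np.pi * np.clip(frac, 0.0, 1.0)), 0.0)
    env9 = np.sin(np.pi * np.clip((9.0 - sunrise) / D, 1e-6, 1.0))
    lognoise = np.exp(rng.normal(0.0, 0.4, n)) if noise else 1.0
    light = np.where(
        daylight,
        spec.indoor_baseline_lux + subject.latent_morning_light * (env / env9) * lognoise,
        spec.evening_baseline_lux)
    light = np.where(asleep, 0.5, light)  # sensor covered / dark bedroom
    if subject.device_brand == "B":
        light = light * spec.light_slope_b

    # --- skin temperature: antiphase to activity
    temp_peak = (peak - 12.0) % 24.0
    temperature = 33.0 + 1.5 * np.cos(2.0 * np.pi * (t_clock - temp_peak) / 24.0)
    if noise:
        temperature = temperature + rng.normal(0.0, 0.15, n)

    # --- off-wrist gaps: zero runs across all channels, in waking hours
    n_gaps = int(rng.poisson(spec.offwrist_rate * n_days))
    native_per_10min = int(round(10.0 / epoch))
    for _ in range(n_gaps):
        # align gaps to the 10-min bin grid so the downstream zero-run
        # rule sees the full injected length
        length = int(rng.integers(10, 31)) * native_per_10min
        day = int(rng.integers(0, n_days))
        wake_start = (onset + dur) % 24.0
        offset_h = float(rng.uniform(0.5, max(24.0 - dur - 1.0, 1.0)))
        start_bin10 = int(((wake_start + offset_h) % 24.0) * 6.0)
        i0 = min(day * per_day + start_bin10 * native_per_10min, n - 1)
        activity[i0:i0 + length] = 0.0
        light[i0:i0 + length] = 0.0
        temperature[i0:i0 + length] = 0.0

    def rec(channel: str, values: np.ndarray) -> ActimetryRecording:
        return ActimetryRecording(subject_id=subject.subject_id,
                                  device_brand=subject.device_brand,
                                  channel=channel, start=start,
                                  epoch_minutes=epoch, values=values)

    return {"activity": rec("activity", activity),
            "light": rec("light", np.asarray(light, dtype=float)),
            "temperature": rec("temperature", temperature)}


def write_cohort_actimetry(cohort: Cohort, directory,
                           n_days: Optional[int] = None) -> List[Path]:
    """Write each subject's recording as a device-dialect CSV.

    Brand-A subjects are written in dialect A (no temperature column),
    brand-B subjects in dialect B, mirroring real device exports.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for subject, mctq in zip(cohort.subjects, cohort.mctq):
        recs = generate_actimetry(subject, cohort.spec, mctq=mctq, n_days=n_days)
        dialect = subject.device_brand
        path = directory / f"{subject.subject_id}_{dialect}.csv"
        write_recording(path, recs, dialect=dialect)
        paths.append(path)
    return paths
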