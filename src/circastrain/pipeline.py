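"""End-to-end study orchestration.

Stages mirror the study design and each stage persists its outputs, so
any suffix of the chain can be re-run from cached files:

1. ``simulate`` -- generate a cohort (covariates, MCTQ, BDI) and write
   per-subject device-dialect actimetry CSVs.
2. ``prep`` -- parse and harmonize recordings: bin to 10 min, rescale
   brand-B light/activity onto the brand-A scale, detect off-wrist
   zero-runs, exclude days with > 4 h missing; emit harmonized CSVs
   and a QC report.
3. ``metrics`` -- select 7- and (when available) 14-day windows and
   compute IS, IV, cosinor parameters, clock-window medians, zeitgeber
   strength and daily profiles.
4. ``stats`` -- descriptive tables, bivariate comparisons, the two
   robust-Poisson model ladders (questionnaire covariates; actimetry
   covariates with season adjustment), 7-vs-14-day agreement, and
   group median profiles with IQR by BDI category.
5. ``report`` -- a JSON index of artifacts with checksums and the
   headline numbers.

Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import actigraphy as ap
from . import metrics as cm
from . import stats as st
from .questionnaires import CATEGORY_GT
from .synthetic import Cohort, CohortSpec, generate_cohort, write_cohort_actimetry

ANALYSIS_WINDOWS = (7, 14)


@dataclass
class StudyConfig:
    """Configuration of one study run."""

    outdir: str = "study_out"
    mode: str = "simulate"  # "simulate" | "files"
    seed: int = 0
    cohort_spec: CohortSpec = None  # type: ignore[assignment]
    cohort_csv: Optional[str] = None  # files mode
    actimetry_dir: Optional[str] = None  # files mode
    bdi_cutoff: int = 10
    sjl_threshold: float = 1.0
    n_days: int = 7  # primary analysis window
    light_unit_lux: float = 500.0
    clock_windows: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(cm.DEFAULT_WINDOWS))
    profile_stat: str = "median"
    activity_scale_b: float = 1.0
    activity_offset_b: float = 0.0
    cross_device_slope: Optional[float] = None  # None -> from cohort spec

    def __post_init__(self) -> None:
        if self.cohort_spec is None:
            self.cohort_spec = CohortSpec(seed=self.seed)
        elif isinstance(self.cohort_spec, dict):
            self.cohort_spec = CohortSpec.from_dict(self.cohort_spec)
        if self.n_days not in ANALYSIS_WINDOWS:
            raise ValueError("n_days must be 7 or 14")
        if self.sjl_threshold <= 0 or self.bdi_cutoff <= 0 or self.light_unit_lux <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


@dataclass
class StudyReport:
    """Bundle of the tables and artifact paths one run produced."""

    config: StudyConfig
    tables: Dict[str, pd.DataFrame]
    qc: dict
    paths: Dict[str, str]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------------
# Stage 1: simulate

def stage_simulate(config: StudyConfig) -> Cohort:
    out = config.out
    cohort = generate_cohort(config.cohort_spec)
    cohort.write(out / "cohort")
    write_cohort_actimetry(cohort, out / "actimetry")
    return cohort


# ---------------------------------------------------------------------------
# Stage 2: prep

def _actimetry_files(config: StudyConfig) -> List[Path]:
    d = Path(config.actimetry_dir) if config.actimetry_dir else config.out / "actimetry"
    return sorted(d.glob("*_[AB].csv"))


def stage_prep(config: StudyConfig) -> dict:
    """Harmonize every recording; returns (and writes) the QC report."""
    out = config.out / "prep"
    out.mkdir(parents=True, exist_ok=True)
    slope = config.cross_device_slope
    if slope is None:
        slope = config.cohort_spec.light_slope_b
    qc: dict = {"subjects": {}, "failures": {}}
    for path in _actimetry_files(config):
        stem = path.stem  # "<sid>_<dialect>"
        sid, dialect = stem.rsplit("_", 1)
        try:
            recs = ap.parse_recording(path, dialect=dialect, subject_id=sid,
                                      device_brand=dialect)
            binned = {c: ap.bin_series(r) for c, r in recs.items()}
            binned["light"] = ap.normalize_light(binned["light"], slope)
            binned["activity"] = ap.normalize_activity(
                binned["activity"], config.activity_scale_b, config.activity_offset_b)
            off = ap.detect_offwrist(binned["activity"])
            masked = ap.apply_offwrist(list(binned.values()), off.mask)
            binned = {r.channel: r for r in masked}
            window = ap.exclude_days(binned["activity"])
            excluded = sorted(str(d) for d in window.missing_per_day
                              if d not in set(window.days))
            eligibility = {}
            for nd in ANALYSIS_WINDOWS:
                sel = ap.select_window(window, nd)
                eligibility[str(nd)] = {"eligible": sel.eligible, "status": sel.status}
            qc["subjects"][sid] = {
                "device_brand": dialect,
                "offwrist_runs": [[int(s), int(l)] for s, l in off.runs],
                "excluded_days": excluded,
                "retained_days": [str(d) for d in window.days],
                "eligibility": eligibility,
            }
            ref = binned["activity"]
            df = pd.DataFrame({"timestamp": [t.isoformat() for t in ref.timestamps()]})
            for chan in ("activity", "light", "temperature"):
                df[chan] = binned[chan].values if chan in binned else np.nan
            df.to_csv(out / f"{sid}.csv", index=False)
        except Exception as exc:  # isolate per-subject failures
            qc["failures"][sid] = f"{type(exc).__name__}: {exc}"
    _write_json(out / "qc.json", qc)
    return qc


# ---------------------------------------------------------------------------
# Stage 3: metrics

def _load_prepped(path: Path, sid: str) -> Dict[str, ap.ActimetryRecording]:
    df = pd.read_csv(path)
    t0 = pd.Timestamp(df["timestamp"].iloc[0]).to_pydatetime()
    t1 = pd.Timestamp(df["timestamp"].iloc[1]).to_pydatetime()
    epoch = (t1 - t0).total_seconds() / 60.0
    recs = {}
    for chan in ("activity", "light", "temperature"):
        vals = df[chan].to_numpy(dtype=float)
        if np.isnan(vals).all():
            continue
        recs[chan] = ap.ActimetryRecording(subject_id=sid, device_brand="harmonized",
                                           channel=chan, start=t0,
                                           epoch_minutes=epoch, values=vals)
    return recs


def stage_metrics(config: StudyConfig) -> Dict[str, pd.DataFrame]:
    prep_dir = config.out / "prep"
    out = config.out / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    metric_rows: List[dict] = []
    window_rows: List[dict] = []
    profile_rows: List[dict] = []
    failures: Dict[str, str] = {}
    for path in sorted(prep_dir.glob("S*.csv")):
        sid = path.stem
        try:
            recs = _load_prepped(path, sid)
            for chan, rec in recs.items():
                days = ap.exclude_days(rec)
                for nd in ANALYSIS_WINDOWS:
                    sel = ap.select_window(days, nd)
                    if not sel.eligible:
                        continue
                    m = cm.compute_metrics(sel)
                    for row in m.rows():
                        metric_rows.append(row)
                    if nd == config.n_days:
                        prof = cm.individual_profile(sel, stat=config.profile_stat)
                        for b, v in enumerate(prof.values):
                            profile_rows.append(dict(subject_id=sid, channel=chan,
                                                     bin=b, value=v))
                    if chan in ("light", "activity"):
                        for wname, cw in config.clock_windows.items():
                            window_rows.append(dict(
                                subject_id=sid, channel=chan, window=wname,
                                n_days_used=nd,
                                median=cm.window_median(sel, cw)))
                    if chan == "light":
                        window_rows.append(dict(
                            subject_id=sid, channel=chan, window="zeitgeber_strength",
                            n_days_used=nd, median=cm.zeitgeber_strength(sel)))
        except Exception as exc:
            failures[sid] = f"{type(exc).__name__}: {exc}"
    tables = {
        "metrics": pd.DataFrame(
            metric_rows, columns=["subject_id", "channel", "metric", "value",
                                  "n_days_used"] if not metric_rows else None),
        "window_medians": pd.DataFrame(
            window_rows, columns=["subject_id", "channel", "window",
                                  "n_days_used", "median"] if not window_rows else None),
        "profiles": pd.DataFrame(
            profile_rows, columns=["subject_id", "channel", "bin",
                                   "value"] if not profile_rows else None),
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    _write_json(out / "metrics_failures.json", failures)
    return tables


# ---------------------------------------------------------------------------
# Stage 4: stats

def descriptives(df: pd.DataFrame, numeric: Sequence[str],
                 binary: Sequence[str]) -> pd.DataFrame:
    """Sample-characteristics summary: median (Q1-Q3) and n (%).

    Quartiles use linear interpolation (type-7) and the midpoint
    convention for even counts; per-variable complete cases.
    """
    rows = []
    for col in numeric:
        v = df[col].dropna().to_numpy(dtype=float)
        if len(v) == 0:
            rows.append(dict(variable=col, kind="numeric", n=0,
                             median=np.nan, q1=np.nan, q3=np.nan, pct=np.nan))
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(dict(variable=col, kind="numeric", n=len(v),
                         median=med, q1=q1, q3=q3, pct=np.nan))
    for col in binary:
        v = df[col].dropna().to_numpy(dtype=float)
        n_pos = int(v.sum())
        rows.append(dict(variable=col, kind="binary", n=len(v), median=np.nan,
                         q1=np.nan, q3=np.nan,
                         pct=100.0 * n_pos / len(v) if len(v) else np.nan))
    return pd.DataFrame(rows)


def _ladder_summary(results: List[st.RegressionResult]) -> pd.DataFrame:
    frames = []
    for res in results:
        f = res.to_frame()
        f.insert(0, "model", res.label)
        f["n"] = res.n
        f["chi2"] = res.chi2
        f["aic"] = res.aic
        f["bic"] = res.bic
        f["pseudo_r2"] = res.pseudo_r2
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _wide_analysis_frame(config: StudyConfig, cohort_df: pd.DataFrame,
                         metrics_df: pd.DataFrame,
                         windows_df: pd.DataFrame) -> pd.DataFrame:
    """Merge questionnaire covariates with actimetry-derived variables."""
    df = cohort_df.copy()
    nd = config.n_days
    if len(metrics_df):
        act = metrics_df[(metrics_df.channel == "activity")
                         & (metrics_df.n_days_used == nd)]
        wide = act.pivot_table(index="subject_id", columns="metric", values="value")
        wide = wide.reindex(columns=["is_scaled", "iv", "acrophase", "amplitude"])
        df = df.merge(wide,
                      left_on="subject_id", right_index=True, how="left")
    if len(windows_df):
        light = windows_df[(windows_df.channel == "light")
                           & (windows_df.n_days_used == nd)
                           & (windows_df.window == "morning")]
        df = df.merge(light.set_index("subject_id")["median"].rename("light_morning"),
                      left_on="subject_id", right_index=True, how="left")
        df["light_morning_unit"] = df["light_morning"] / config.light_unit_lux
    return df


def _agreement_7v14(metrics_df: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation and Bland-Altman bias, 7- vs 14-day estimates."""
    rows = []
    if not len(metrics_df):
        return pd.DataFrame(rows)
    for (chan, metric), grp in metrics_df.groupby(["channel", "metric"]):
        if metric not in ("is_scaled", "iv", "acrophase", "amplitude"):
            continue
        wide = grp.pivot_table(index="subject_id", columns="n_days_used",
                               values="value").dropna()
        if wide.shape[1] < 2 or len(wide) < 3:
            continue
        a, b = wide[7].to_numpy(), wide[14].to_numpy()
        rho = st.spearman(a, b)
        ba = st.bland_altman(a, b)
        rows.append(dict(channel=chan, metric=metric, n=len(wide),
                         spearman_rho=rho.statistic, spearman_p=rho.p_value,
                         bias=ba.bias, loa_lower=ba.loa_lower, loa_upper=ba.loa_upper))
    return pd.DataFrame(rows)


def stage_stats(config: StudyConfig) -> Dict[str, pd.DataFrame]:
    out = config.out / "tables"
    out.mkdir(parents=True, exist_ok=True)
    cohort_df = pd.read_csv(config.cohort_csv or config.out / "cohort" / "cohort.csv")
    mdir = config.out / "metrics"
    metrics_df = pd.read_csv(mdir / "metrics.csv") if (mdir / "metrics.csv").exists() \
        else pd.DataFrame(columns=["subject_id", "channel", "metric", "value", "n_days_used"])
    windows_df = pd.read_csv(mdir / "window_medians.csv") if (mdir / "window_medians.csv").exists() \
        else pd.DataFrame(columns=["subject_id", "channel", "window", "n_days_used", "median"])
    profiles_df = pd.read_csv(mdir / "profiles.csv") if (mdir / "profiles.csv").exists() \
        else pd.DataFrame(columns=["subject_id", "channel", "bin", "value"])

    df = _wide_analysis_frame(config, cohort_df, metrics_df, windows_df)
    tables: Dict[str, pd.DataFrame] = {}

    # Table-1-style descriptives, separately per instrument subsample
    desc_all = descriptives(
        df, numeric=["age", "msw", "msf", "sleep_duration_w", "sleep_duration_f",
                     "time_outdoors_w", "time_outdoors_f", "sjl", "bdi_sum"],
        binary=["female", "bdi_gt10", "sjl_gt_1h"])
    desc_all.insert(0, "sample", "questionnaires")
    acti_ids = set(metrics_df.subject_id.unique()) if len(metrics_df) else set()
    desc_acti = descriptives(
        df[df.subject_id.isin(acti_ids)],
        numeric=[c for c in ("age", "msf", "sjl", "bdi_sum", "light_morning")
                 if c in df],
        binary=["female", "bdi_gt10"])
    desc_acti.insert(0, "sample", "actimetry")
    tables["descriptives"] = pd.concat([desc_all, desc_acti], ignore_index=True)

    # bivariate comparisons by BDI category
    biv_rows = []
    grp_pos = df[df.bdi_gt10 == 1]
    grp_neg = df[df.bdi_gt10 == 0]
    for col in ["sjl", "msf", "light_morning", "is_scaled", "iv", "acrophase",
                "amplitude"]:
        if col not in df:
            continue
        x = grp_pos[col].dropna()
        y = grp_neg[col].dropna()
        if len(x) == 0 or len(y) == 0:
            continue
        res = st.wilcoxon_mann_whitney(x, y)
        biv_rows.append(dict(variable=col, test=res.test, statistic=res.statistic,
                             p=res.p_value, n1=res.n1, n2=res.n2))
    ct = pd.crosstab(df.sjl_gt_1h, df.bdi_gt10)
    if ct.shape == (2, 2):
        chi = st.chi_square_2x2(ct.to_numpy())
        biv_rows.append(dict(variable="sjl_gt_1h x bdi_gt10", test=chi.test,
                             statistic=chi.statistic, p=chi.p_value,
                             n1=chi.n1, n2=None))
    tables["bivariates"] = pd.DataFrame(biv_rows)

    # questionnaire model ladder (age/sex, +outdoors, +MSF, +SJL>1h);
    # failing models (e.g. collinear terms in tiny cohorts) are skipped
    # individually so the rest of the report survives
    mctq_specs = [["age", "female"],
                  ["age", "female", "time_outdoors_f"],
                  ["age", "female", "time_outdoors_f", "msf"],
                  ["age", "female", "time_outdoors_f", "msf", "sjl_gt_1h"]]
    mctq_models = []
    for i, terms in enumerate(mctq_specs):
        try:
            mctq_models.extend(st.model_ladder(df, "bdi_gt10", [terms],
                                               labels=[f"Model {i + 1}"]))
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"questionnaire model {i + 1} not fit: {exc}")
    tables["mctq_models"] = _ladder_summary(mctq_models) if mctq_models else pd.DataFrame()

    # actimetry ladder: full model then one-pass parsimony reduction,
    # never dropping the age/sex/season adjusters
    acti_terms = ["age", "female", "season_mar_sep", "light_morning_unit",
                  "acrophase", "is_scaled"]
    acti_df = df.dropna(subset=[t for t in acti_terms if t in df] + ["bdi_gt10"])
    tables["actimetry_models"] = pd.DataFrame()
    if len(acti_df) >= 20 and all(t in acti_df for t in acti_terms):
        try:
            full, reduced = st.reduce_model(
                acti_df, "bdi_gt10", acti_terms,
                tested=["light_morning_unit", "acrophase", "is_scaled"],
                labels=("Model 1 (full)", "Model 2 (reduced)"))
            tables["actimetry_models"] = _ladder_summary([full, reduced])
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"actimetry model ladder not fit: {exc}")

    tables["agreement_7v14"] = _agreement_7v14(metrics_df)

    # group median profiles with IQR by BDI category
    gp_rows = []
    if len(profiles_df):
        merged = profiles_df.merge(df[["subject_id", "bdi_gt10"]], on="subject_id")
        for (chan, grp_label), g in merged.groupby(["channel", "bdi_gt10"]):
            wide = g.pivot_table(index="subject_id", columns="bin", values="value")
            vals = wide.to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(vals, axis=0)
                q1 = np.nanpercentile(vals, 25, axis=0)
                q3 = np.nanpercentile(vals, 75, axis=0)
            for b in range(vals.shape[1]):
                gp_rows.append(dict(channel=chan,
                                    group=("BDI>10" if grp_label == 1 else "BDI<=10"),
                                    bin=b, median=med[b], q1=q1[b], q3=q3[b],
                                    n=len(wide)))
    tables["group_profiles"] = pd.DataFrame(gp_rows)

    for name, t in tables.items():
        t.to_csv(out / f"{name}.csv", index=False)
    return tables


# ---------------------------------------------------------------------------
# Stage 5: report

def stage_report(config: StudyConfig) -> dict:
    out = config.out
    artifacts = {}
    for sub in ("cohort", "prep", "metrics", "tables"):
        d = out / sub
        if not d.exists():
            continue
        for p in sorted(d.rglob("*")):
            if p.is_file():
                artifacts[str(p.relative_to(out))] = _sha256(p)
    summary = {}
    coh = out / "cohort" / "cohort.csv"
    if coh.exists():
        df = pd.read_csv(coh)
        summary["n_subjects"] = int(len(df))
        summary["bdi_gt10_pct"] = round(100.0 * df.bdi_gt10.mean(), 4)
        summary["sjl_gt_1h_pct"] = round(100.0 * df.sjl_gt_1h.mean(), 4)
    report = {"seed": config.seed, "n_days": config.n_days,
              "artifacts": artifacts, "summary": summary}
    _write_json(out / "report.json", report)
    return report


def run_study(config: StudyConfig) -> StudyReport:
    """Run every stage in order and return the assembled report."""
    config.out.mkdir(parents=True, exist_ok=True)
    if config.mode == "simulate":
        stage_simulate(config)
    elif config.mode != "files":
        raise ValueError("mode must be 'simulate' or 'files'")
    qc = stage_prep(config)
    stage_metrics(config)
    tables = stage_stats(config)
    report = stage_report(config)
    paths = {k: str(config.out / k) for k in ("report.json",)}
    return StudyReport(config=config, tables=tables, qc=qc, paths=paths)
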