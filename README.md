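# circastrain

Circadian strain, light exposure and depressive symptoms: a tested,
reusable analysis chain for wrist-actimetry recordings and chronotype /
mood questionnaires.

## The scientific problem

Irregular light–dark cycles and misalignment between biological and
social time ("circadian strain") are candidate risk factors for
depressive symptoms. In field studies this question is approached with
two kinds of data:

* **Questionnaires** — the Munich ChronoType Questionnaire (MCTQ)
  yields midsleep on workdays (MSW) and work-free days (MSF, a
  phase-of-entrainment marker) and **social jetlag**
  (SJL = |MSF − MSW|, hours); the Beck Depression Inventory (BDI,
  21 items scored 0–3) yields a symptom sum, with sum > 10 marking
  clinically significant symptoms.
* **Wrist actimetry** — activity counts, ambient light (lux) and skin
  temperature recorded continuously for 1–2 weeks, from which
  nonparametric rhythm metrics are computed:
  * inter-daily stability IS = N Σ_b (x̄_b − x̄)² / (P Σ_i (x_i − x̄)²) ∈ [0, 1],
  * intra-daily variability IV = N Σ (x_i − x_{i−1})² / ((N−1) Σ (x_i − x̄)²) (≈2 for white noise),
  * 24-h cosinor parameters x(t) = MESOR + A·cos(2π(t − φ)/24)
    (amplitude A, acrophase φ),
  * median light/activity in clock windows (day 7:00–17:00, morning
    8:00–10:00, afternoon 13:00–15:00, night 20:00–1:00) and the
    zeitgeber-strength ratio morning/evening light.

Associations with the binary outcome BDI > 10 are estimated with
**modified Poisson regression**: a Poisson log-link GLM whose
exponentiated coefficients are prevalence ratios (PR), with
heteroskedasticity-robust HC0 sandwich variance (the Poisson variance
is misspecified — typically under-dispersed — for a binary outcome).

Because individual-level field data of this kind are generally not
shareable, the package ships a first-class **synthetic cohort
generator** whose defaults emulate the study conditions the analysis
is designed for: ~22% baseline prevalence of BDI > 10, a
near-zero-inflated SJL distribution, PR 2.19 for SJL > 1 h, PR 0.48
per 500 lx of morning light, photoperiod-gated light profiles at
~29° S, unimodal daytime activity, antiphase skin temperature, two
device dialects with a cross-device light scale, and injected
off-wrist gaps. Every downstream stage is testable against the known
generating model.

## Worked example

```python
from circastrain import CohortSpec, generate_cohort, robust_poisson

spec = CohortSpec(n_subjects=2000, seed=1)
df = generate_cohort(spec).to_frame()
res = robust_poisson(df["bdi_gt10"], df[["sjl_gt_1h", "morning_light_500"]])
print(res.to_frame().round(3).to_string(index=False))
```

prints

```
             term  estimate  ci_low  ci_high    se   p stars
      (Intercept)    -1.683     NaN      NaN 0.108 0.0    **
        sjl_gt_1h     2.588   2.077    3.223 0.112 0.0    **
morning_light_500     0.539   0.433    0.670 0.111 0.0    **
```

Read: subjects with SJL > 1 h have 2.59 times the prevalence of
clinically significant depressive symptoms (robust 95% CI 2.08–3.22);
each additional 500 lx of median morning light is associated with a
46% lower prevalence (PR 0.54, CI 0.43–0.67). Both estimates are one
seeded draw around the generating values 2.19 and 0.48. The intercept
is the log prevalence at reference covariates.

Circadian metrics for one generated subject:

```python
from circastrain import (generate_actimetry, bin_series, detect_offwrist,
                         apply_offwrist, exclude_days, select_window,
                         compute_metrics)

cohort = generate_cohort(CohortSpec(n_subjects=3, seed=1))
s, m = cohort.subjects[0], cohort.mctq[0]
recs = generate_actimetry(s, spec, mctq=m)
act = bin_series(recs["activity"])                      # 10-min bins
act = apply_offwrist([act], detect_offwrist(act).mask)[0]
window = select_window(exclude_days(act), n_days=7)
mt = compute_metrics(window)
print(f"IS={mt.is_scaled:.1f}  IV={mt.iv:.2f}  "
      f"acrophase={mt.acrophase:.2f} h  amplitude={mt.amplitude:.0f}")
```

prints `IS=88.5  IV=0.25  acrophase=14.79 h  amplitude=236` — a
stable (IS 88.5/100), smooth (IV 0.25) rest–activity rhythm peaking
mid-afternoon.

The full study — cohort, device CSVs, harmonization, QC, metrics,
descriptive and regression tables, group profiles — runs from the
shell:

```sh
circastrain run-all --seed 1 --out study_out
```

and is byte-for-byte reproducible for a fixed seed. Individual stages
(`simulate`, `prep`, `metrics`, `stats`, `report`) re-run from each
other's cached outputs.

## Layout

* `circastrain.questionnaires` — MCTQ clock arithmetic, SJL, BDI
  scoring (single-missing-item rule), Cronbach's alpha, corrected
  item-total correlations.
* `circastrain.actigraphy` — device CSV dialects, 10-min binning,
  off-wrist zero-run detection, day exclusion (> 4 h missing), 7/14-day
  window selection, cross-device light/activity harmonization.
* `circastrain.metrics` — IS, IV, cosinor, daily profiles (individual
  and group with IQR), clock-window medians, zeitgeber strength.
* `circastrain.stats` — Wilcoxon–Mann–Whitney, 2×2 chi-square,
  Spearman, Bland–Altman, robust (HC0) Poisson prevalence-ratio
  models, model ladders with one-pass parsimony reduction.
* `circastrain.synthetic` — cohort and actimetry generator.
* `circastrain.pipeline` / `circastrain.cli` — staged orchestration
  and the `circastrain` command.

See `docs/methods.md` for the modelling choices and their rationale.
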