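# Methods

This note documents the models, conventions and design choices behind
`circastrain`, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Questionnaire variables

Clock times are decimal hours in [0, 24) (or `"HH:MM"` strings).
Sleep duration wraps midnight: duration = (offset − onset) mod 24,
with equal onset/offset rejected as ambiguous (0 vs 24 h). Midsleep is
onset + duration/2 mod 24.

**Social jetlag** is the absolute shorter-arc circular difference
between midsleep on free days (MSF) and workdays (MSW), in [0, 12] h.
Questionnaire sign conventions vary across studies; only nonnegative
SJL is analyzed here, and the signed shorter-arc difference
(positive = later on free days) is available via `signed=True`.
No alarm-clock correction and no sleep-corrected chronotype (MSFsc)
are computed: MSF itself is used as the phase-of-entrainment marker.
SJL is dichotomized at > 1 h (strict inequality), the upper-quartile
convention for low-SJL rural populations; the threshold is a
parameter.

**BDI scoring.** 21 items in {0..3}; sum > 10 = clinically
significant symptoms. With exactly one missing item the sum is
reported missing but the binary category is still resolved when it is
decidable either way: partial sum ≥ 11 already exceeds the cut-off,
and partial sum ≤ 7 cannot reach it even if the missing item were 3
(total < 8 ≤ 10). Anything between is indeterminate, as is more than
one missing item. This rule is verified in the tests by exhaustive
enumeration of the missing item over {0,1,2,3} for every partial sum.

**Cronbach's alpha** uses population (divide-by-n) variances on
complete cases; the coefficient is invariant to the variance
denominator as long as it is used consistently in numerator and
denominator. Whether complete-case was the right analysis set is a
judgment call; it is the conservative default for internal-consistency
coefficients. Corrected item-total correlations are Pearson
correlations of each item with the sum of the remaining items;
zero-variance items yield NaN rather than an arbitrary value.

## Actimetry preprocessing

* **Binning.** Native epochs are aggregated to 10-min bins: activity
  by sum (counts are additive), light and temperature by mean. A
  binned value is missing iff all native epochs in it are missing;
  partially observed bins aggregate the observed epochs. The
  aggregation is per-channel configurable since devices and studies
  differ.
* **Off-wrist detection.** Maximal runs of ≥ 10 consecutive zero
  10-min activity bins are masked on every channel of the subject (a
  removed watch records no meaningful light or temperature either).
  The flagged runs are returned as an auditable list — an automated
  stand-in for manual visual confirmation. Shorter zero runs are left
  alone: genuine motionless rest produces them.
* **Day exclusion.** Analysis days run midnight-to-midnight in naive
  local time (no DST adjustment; rural field setting). A day is
  excluded only when missing time exceeds 4 h — 24 missing 10-min
  bins retain the day, 25 exclude it. Partial first/last days are not
  counted as days.
* **Window selection.** The earliest block of 7 (or 14) consecutive
  retained calendar days is selected; any such block contains each
  weekday exactly once (or twice), balancing workday/free-day
  structure. Subjects without a qualifying block are marked ineligible
  with an explicit status, never silently dropped.
* **Harmonization.** Brand-B light is divided by the through-origin
  least-squares slope (Σab/Σa²) of a simultaneous dual-device wear,
  putting it on the brand-A lux scale; an intercept variant exists
  behind a flag but the default follows the slope-only convention.
  The brand-B activity transform is an affine map whose parameters
  are configuration (manufacturer recommendations are not published
  as code).

## Circadian metrics

IS and IV are computed on the 10-min bin basis (P = 144 bins/day),
matching the preprocessing, not on hourly means — values are
therefore not directly comparable to hourly-basis implementations
(which typically report higher IS). Missing bins are skipped; IV
treats the multi-day window as one continuous sequence (day
boundaries are not breaks) and drops difference pairs spanning a
missing bin.

One deliberate deviation from the classical presentation: the IS
variance ratio is bounded by 1 only for fully observed windows. With
unbalanced missingness the between-bin means are no longer a
projection of the observed data and the ratio can exceed 1 slightly
(values up to ~1.08 were observed on small fixtures, ~1.01 on
realistic off-wrist-masked data). The implementation therefore raises
on a >1 result only when the window is fully observed (a genuine
inconsistency) and otherwise clamps to 1 with a warning.

The cosinor is an ordinary least-squares fit of
M + β_c cos(ωt) + β_s sin(ωt), ω = 2π/24 h⁻¹, on the non-missing bin
starts; amplitude = √(β_c² + β_s²), acrophase = atan2(β_s, β_c)·24/2π
mod 24, reported in decimal hours. A constant input yields amplitude
0 with the acrophase flagged undefined (NaN); a design with too few
distinct clock times raises. The fit uses the raw binned data rather
than the median daily profile — all observations contribute, and the
profile-based variant can be obtained by fitting
`individual_profile` output.

Daily profiles use per-bin medians (midpoint convention for even
counts) across retained days; group profiles take per-bin median and
quartiles (linear-interpolation, type-7) across subjects.
Clock-window medians pool all non-missing bins whose start lies in
the half-open window, across days; the night window 20:00–1:00 wraps
midnight (30 bins/day). Zeitgeber strength is the morning/evening
median-light ratio (defaults 8:00–10:00 over 20:00–1:00, both
configurable); a zero evening median leaves it undefined (NaN with a
warning), never infinite.

## Association statistics

Wilcoxon–Mann–Whitney U is reported for the first group, with exact
enumeration when n₁n₂ ≤ 400 and the pooled sample is tie-free,
otherwise the tie-corrected normal approximation (continuity
correction off by default). The 2×2 chi-square is Pearson's without
Yates correction (the standard choice for n > 40; correction behind a
flag). Spearman uses average ranks; Bland–Altman reports
bias = mean(a−b) and bias ± 1.96·sd (n−1 denominator).

**Modified Poisson regression.** Fit by IRLS (statsmodels GLM,
Poisson family, log link; deviance tolerance 1e-8, max 100
iterations). The covariance is the HC0 sandwich: inverse Fisher
information as bread, Σ xᵢxᵢᵀ(yᵢ−μ̂ᵢ)² as meat — for the Poisson
log-link the observed and expected information coincide, so this is
the standard estimating-equation sandwich. Wald 95% CIs are formed on
the linear scale and exponentiated; the intercept is reported raw by
convention. Model χ² is the likelihood ratio against the
intercept-only model; AIC = −2ℓ + 2k, BIC = −2ℓ + k ln n on the
Poisson likelihood (the y! term vanishes for binary y); pseudo-R² is
Cragg–Uhler, [1 − (L₀/L₁)^{2/n}]/[1 − L₀^{2/n}]. Fitted prevalences
collapsing to ~0 on a stratum trigger a separation warning naming the
constant terms. Missing covariates are handled complete-case per
model, so n can differ between models with different instruments.

Model ladders mirror the two-table design: a questionnaire ladder
(age+sex; +time outdoors on free days; +MSF; +SJL > 1 h) and an
actimetry ladder (age, sex, season, morning light per 500 lx,
activity acrophase, IS 0–100) reduced in a single pass — tested
factors with robust Wald p > 0.05 are dropped together, adjusters
(age/sex/season) never. One-pass rather than iterative stepwise
matches the two-model (full/reduced) presentation and avoids
stepwise's inferential pathologies.

## The synthetic cohort

The generator's defaults are the study conditions the analysis
assumes, fixed once:

| parameter | default | meaning |
|---|---|---|
| `prevalence_base` | 0.22 | P(BDI > 10) at reference covariates |
| `pr_sjl` | 2.19 | prevalence ratio for SJL > 1 h |
| `pr_light_500lx` | 0.48 | prevalence ratio per 500 lx morning light |
| `sex_ratio` | 0.56 | fraction female |
| `age_range` | 16–92 | uniform ages, years |
| `season_mix` | 0.5 | fraction recorded Mar 20–Sep 22 |
| `device_mix` | 0.47 | fraction wearing brand B (with temperature) |
| `light_slope_b` | 1.5 | brand-B lux scale relative to brand A |
| `n_days` | 14 | recording length (≥ 14) |
| `offwrist_rate` | 0.1 | expected off-wrist gaps per day |
| `latitude` | −29.0° | photoperiod model input |
| `morning_light_median`, `_sigma` | 400 lx, 0.75 | lognormal latent morning light |
| `sjl_zero_mass`, `sjl_mean_hours` | 0.30, 0.75 | zero-inflated exponential SJL |

BDI positivity is drawn from the log-linear model
P = base · pr_sjl^{[SJL>1h]} · pr_light^{lux/500}, truncated to 1
(or rejected with an explicit message under `strict=True`); the item
vector is then allocated to a consistent sum (≤ 10 or ≥ 11) by seeded
sequential allocation over the 21 items capped at 3. The indicator
uses the *realized* (15-min-quantized) SJL, so regression on the
emitted table recovers the generating ratios without attenuation.
Item-level realism (low endorsement of suicidal-thoughts and
weight-loss items) is a config option, off by default — per-item
distributions are essentially unconstrained by available evidence.

Sleep times are quantized to 15 min to mimic questionnaire reporting;
free-day midsleep is delayed relative to workdays by the latent SJL.
The SJL mixture (30% exact zeros, exponential mean 0.75 h otherwise)
reproduces quartiles starting at 0 with a median near 0.25 h and
roughly a fifth of subjects above 1 h.

Actimetry is generated at a 5-min native epoch. Light is a
photoperiod-gated sine envelope — day length from the simple cosine
model 12 + (24/π)asin(tan|φ|·tan 23.44°)·cos(2π(doy−172)/365.25)
(hemisphere-signed), not an ephemeris — scaled so the 8:00–10:00
median tracks the subject's latent morning light, over a ~2 lx
evening baseline and a 0.5 lx sleep floor, with lognormal epoch
noise. Activity is a half-cosine daytime bump (10-h support, peak
near 14:00 with per-subject jitter) over a positive wake baseline,
multiplied by subject-specific lognormal burst noise, near-zero
(Poisson mean 1/epoch) during the reported workday sleep window.
Skin temperature is a 24-h cosine in antiphase to the activity peak.
Off-wrist gaps are zero-runs across all channels, aligned to the
10-min grid (lengths 10–30 bins, uniform), placed in waking hours;
at the 0.1/day default roughly a third of 14-day recordings lose at
least one day to the 4-h rule, while 7-day eligibility stays near
universal — matching a protocol in which whole-day exclusions are
rare.

**What the generator does not emulate:** posture/clothing sensor
occlusion, daylight weather variability, naps and split sleep,
weekday/weekend activity structure, device-specific noise spectra,
age- or sex-dependent rhythm differences, and any community-level
geography. Passing tests therefore demonstrate correctness of the
computational chain and recoverability of effects under the assumed
structure — not that the effects exist in any real population.

## Pipeline and numerics

The staged pipeline persists every intermediate product (device CSVs,
harmonized 10-min CSVs, QC JSON, tidy metric/window/profile tables,
result tables, a checksummed report index), so any suffix of stages
re-runs from cache and a fixed seed reproduces every artifact
byte-for-byte. Per-subject failures in prep/metrics are isolated and
listed in the QC report; models that cannot be fit (e.g. collinear
terms in tiny cohorts) are skipped individually with a warning.
Percentages are rounded only in rendered summaries; machine-readable
outputs keep full precision. Default problem sizes (210-subject
cohorts, 14-day recordings, 2,000-subject recovery cohorts, 50–100
replicate checks) were chosen so the whole validation chain runs in
minutes on one CPU.

## Known limitations

* Acrophase near-zero amplitude is numerically unstable by nature;
  the fit flags amplitude ≤ 1e-12·scale as undefined rather than
  reporting a meaningless phase.
* IS/IV on sparse, unbalanced windows are estimator-dependent; see
  the clamping rule above.
* The cross-device activity transform is configuration, not data:
  no public reference transform exists.
* Exact vs asymptotic Wilcoxon p-values differ slightly in small
  samples; the switch rule (n₁n₂ ≤ 400, tie-free) is documented
  and deterministic.
* No mixed-effects/community clustering and no multiple-testing
  correction are implemented — out of scope for this design.
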