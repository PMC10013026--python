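"""Group comparisons, agreement analyses and robust Poisson models.

The central model is the modified Poisson regression for a binary
outcome: a Poisson GLM with log link whose exponentiated coefficients
are prevalence ratios (PR), paired with a heteroskedasticity-robust
HC0 sandwich covariance to repair the misspecified Poisson variance
(these models are typically under-dispersed on binary data).  Fitting
is delegated to statsmodels GLM/IRLS; this module owns the result
contract: PRs, robust Wald CIs, likelihood-ratio model chi-square,
AIC/BIC on the Poisson likelihood, and the Cragg-Uhler (Nagelkerke)
pseudo-R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass
class ComparisonResult:
    """One bivariate test: statistic, p-value and group sizes."""

    test: str
    statistic: float
    p_value: float
    n1: int
    n2: Optional[int] = None
    note: Optional[str] = None


def wilcoxon_mann_whitney(x, y, continuity: bool = False) -> ComparisonResult:
    """Wilcoxon-Mann-Whitney rank-sum test; U reported for the first group.

    Uses exact enumeration when n1*n2 <= 400 and the pooled sample is
    tie-free, otherwise the normal approximation with tie correction
    (plain, no continuity correction, unless ``continuity=True``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                   use_continuity=continuity)
    return ComparisonResult(test="wilcoxon_mann_whitney", statistic=float(res.statistic),
                            p_value=float(res.pvalue), n1=len(x), n2=len(y),
                            note=method)


def chi_square_2x2(table, correction: bool = False) -> ComparisonResult:
    """Pearson chi-square for a 2x2 table, df = 1.

    Closed form n(ad - bc)^2 / (r1 r2 c1 c2); Yates continuity
    correction off by default (the usual convention for n > 40) and
    available via ``correction=True``.  All margins must be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins must be positive")
    det = a * d - b * c
    if correction:
        num = n * max(abs(det) - n / 2.0, 0.0) ** 2
    else:
        num = n * det ** 2
    chi2 = num / (r1 * r2 * c1 * c2)
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return ComparisonResult(test="chi_square_2x2", statistic=float(chi2), p_value=p,
                            n1=int(n))


def spearman(x, y) -> ComparisonResult:
    """Spearman rank correlation with average ranks for ties, two-sided p.

    A constant input leaves the correlation undefined: NaN is returned
    with an explanatory note rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ComparisonResult(test="spearman", statistic=float("nan"),
                                p_value=float("nan"), n1=len(x),
                                note="undefined: constant input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = scipy.stats.spearmanr(x, y)
    return ComparisonResult(test="spearman", statistic=float(rho), p_value=float(p),
                            n1=len(x))


@dataclass
class BlandAltmanResult:
    """Agreement between two measurements of the same quantity."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(a-b), LoA = bias +/- 1.96 sd.

    The standard deviation of the differences uses the n-1 denominator.
    Per-pair means are returned for plotting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_lower=bias - 1.96 * sd,
                             loa_upper=bias + 1.96 * sd, sd_diff=sd,
                             means=(a + b) / 2.0, diffs=diffs)


@dataclass
class RegressionResult:
    """Modified-Poisson fit in the layout of an epidemiological results table.

    ``coef`` are raw (log-scale) coefficients; ``pr`` and the CI
    bounds are exponentiated (prevalence ratios) for slope terms.  The
    intercept is conventionally reported raw.
    """

    terms: List[str]
    coef: np.ndarray
    se_robust: np.ndarray
    p_values: np.ndarray
    pr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    chi2: float
    chi2_df: int
    chi2_p: float
    aic: float
    bic: float
    pseudo_r2: float
    llf: float
    llnull: float
    label: str = ""

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    def to_frame(self) -> pd.DataFrame:
        """One row per term with PR, robust 95% CI and significance stars."""
        stars = np.where(self.p_values < 0.01, "**",
                         np.where(self.p_values < 0.05, "*", ""))
        rows = []
        for i, t in enumerate(self.terms):
            if t == "const":
                rows.append(dict(term="(Intercept)", estimate=self.coef[i],
                                 ci_low=np.nan, ci_high=np.nan,
                                 se=self.se_robust[i], p=self.p_values[i],
                                 stars=stars[i]))
            else:
                rows.append(dict(term=t, estimate=self.pr[i],
                                 ci_low=self.ci_low[i], ci_high=self.ci_high[i],
                                 se=self.se_robust[i], p=self.p_values[i],
                                 stars=stars[i]))
        df = pd.DataFrame(rows)
        df.attrs.update(n=self.n, chi2=self.chi2, aic=self.aic, bic=self.bic,
                        pseudo_r2=self.pseudo_r2)
        return df


def _design_matrix(design, add_intercept: bool) -> Tuple[np.ndarray, List[str]]:
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        terms = [f"x{i}" for i in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        terms = ["const"] + terms
    return X, terms


def robust_poisson(outcome, design, add_intercept: bool = True,
                   label: str = "") -> RegressionResult:
    """Poisson log-link regression of a binary outcome with HC0 variance.

    Fit by IRLS to convergence (deviance change < 1e-8, max 100
    iterations).  The HC0 sandwich uses the inverse Fisher information
    as bread and sum x_i x_i' (y_i - mu_i)^2 as meat.  95% Wald CIs are
    formed on the linear scale and exponentiated.  The model
    chi-square is the likelihood ratio against the intercept-only
    model; AIC = -2l + 2k, BIC = -2l + k ln n, and the Cragg-Uhler
    pseudo-R^2 rescales the likelihood-ratio index.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1)")
    X, terms = _design_matrix(design, add_intercept)
    if len(y) != len(X):
        raise ValueError("outcome and design have different lengths")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design: terms {terms} are collinear")

    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(cov_type="HC0", maxiter=100, tol=1e-8)
    if not getattr(res, "converged", True):
        raise RuntimeError(
            "IRLS did not converge within 100 iterations; deviance trace: "
            f"{res.fit_history.get('deviance', [])}")
    mu = res.mu
    if np.min(mu) < 1e-10:
        bad = [terms[j] for j in range(X.shape[1])
               if j > 0 and np.ptp(X[mu < 1e-10, j]) == 0]
        warnings.warn(f"possible separation: fitted prevalence ~0 on a stratum "
                      f"(constant terms there: {bad})")

    k = X.shape[1]
    n = len(y)
    llf = float(res.llf)
    null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Poisson()).fit()
    llnull = float(null.llf)
    n_slopes = k - (1 if add_intercept else 0)
    chi2 = 2.0 * (llf - llnull)
    chi2_p = float(scipy.stats.chi2.sf(chi2, df=max(n_slopes, 1)))
    aic = -2.0 * llf + 2.0 * k
    bic = -2.0 * llf + k * np.log(n)
    # Cragg-Uhler: [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)]
    denom = 1.0 - np.exp(2.0 * llnull / n)
    pseudo_r2 = float((1.0 - np.exp(2.0 * (llnull - llf) / n)) / denom) if denom != 0 else float("nan")

    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)  # robust: cov_type was HC0
    ci = np.asarray(res.conf_int(), dtype=float)
    p_values = np.asarray(res.pvalues, dtype=float)
    return RegressionResult(
        terms=terms, coef=coef, se_robust=se, p_values=p_values,
        pr=np.exp(coef), ci_low=np.exp(ci[:, 0]), ci_high=np.exp(ci[:, 1]),
        n=n, chi2=float(chi2), chi2_df=max(n_slopes, 1), chi2_p=chi2_p,
        aic=float(aic), bic=float(bic), pseudo_r2=pseudo_r2,
        llf=llf, llnull=llnull, label=label)


def model_ladder(data: pd.DataFrame, outcome: str,
                 specs: Sequence[Sequence[str]],
                 labels: Optional[Sequence[str]] = None) -> List[RegressionResult]:
    """Fit an ordered sequence of models (complete cases per model)."""
    results = []
    labels = list(labels) if labels is not None else [f"Model {i + 1}" for i in range(len(specs))]
    for label, terms in zip(labels, specs):
        terms = list(terms)
        sub = data[[outcome] + terms].dropna()
        results.append(robust_poisson(sub[outcome], sub[terms], label=label))
    return results


def reduce_model(data: pd.DataFrame, outcome: str, terms: Sequence[str],
                 tested: Sequence[str], alpha: float = 0.05,
                 labels: Tuple[str, str] = ("full", "reduced")) -> Tuple[RegressionResult, RegressionResult]:
    """Full model, then one-pass parsimony reduction.

    Tested factors whose robust Wald p exceeds ``alpha`` in the full
    model are dropped in a single pass; adjusters (any term not listed
    in ``tested``) are never dropped.  Returns (full, reduced); when
    nothing is dropped the reduced model equals the full one.
    """
    terms = list(terms)
    tested = [t for t in tested if t in terms]
    sub = data[[outcome] + terms].dropna()
    full = robust_poisson(sub[outcome], sub[terms], label=labels[0])
    drop = [t for t in tested if full.p_values[full.term_index(t)] > alpha]
    kept = [t for t in terms if t not in drop]
    sub2 = data[[outcome] + kept].dropna()
    reduced = robust_poisson(sub2[outcome], sub2[kept], label=labels[1])
    return full, reduced
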