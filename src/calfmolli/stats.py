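"""The study's statistical layer.

Two-group comparisons are gated on normality: each group is tested with
Shapiro–Wilk, and both passing at the gate level sends the variable to an
independent-samples Student's t-test, otherwise to the two-sided
Mann–Whitney–Wilcoxon test; the summary format follows the branch
(mean ± sd for normal, median (IQR) otherwise).  Categorical group
differences use the Fisher exact or Pearson chi-square test.  Associations
between imaging metrics and clinical markers use univariate ordinary least
squares, reporting the standardized coefficient, raw slope with standard
error, R², adjusted r² and the two-sided slope p-value.  Intra-observer
reliability uses the two-way random-effects, absolute-agreement,
average-measures intraclass correlation ICC(2,k) with its F-based 95%
confidence interval; agreement above 0.7 is flagged excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "IccResult",
    "compare_groups",
    "categorical_test",
    "univariate_regression",
    "icc_two_way_average",
]

ICC_EXCELLENT = 0.7


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p_value: float
    normality_p: tuple[float, float]
    summary_a: str
    summary_b: str
    n: tuple[int, int]


@dataclass(frozen=True)
class RegressionResult:
    n: int
    beta_std: float
    slope_raw: float
    slope_se: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two_way_random_average"

    @property
    def excellent(self) -> bool:
        return self.icc > ICC_EXCELLENT


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.4g} ± {x.std(ddof=1):.4g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g} ({q1:.4g}–{q3:.4g})"


def compare_groups(
    values_a, values_b, alpha: float = 0.05, variable: str = ""
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Both groups normal by Shapiro–Wilk at ``alpha`` -> two-sided Student's
    t-test; otherwise two-sided Mann–Whitney–Wilcoxon (exact for small
    groups without ties, tie-corrected normal approximation otherwise).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"need >= 3 observations per group, got {a.size} and {b.size}"
        )
    pa = float(sps.shapiro(a).pvalue)
    pb = float(sps.shapiro(b).pvalue)
    normal = pa >= alpha and pb >= alpha
    if normal:
        res = sps.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        small = min(a.size, b.size) <= 8
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney"
    return GroupComparison(
        variable=variable,
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=(pa, pb),
        summary_a=_summary(a, normal),
        summary_b=_summary(b, normal),
        n=(int(a.size), int(b.size)),
    )


def categorical_test(table, rule: str = "observed") -> tuple[float, str]:
    """Group-difference test for a contingency table of counts.

    For 2x2 tables the Fisher exact test is used when any cell is small,
    the Pearson chi-square (uncorrected) otherwise; larger tables use
    chi-square.  ``rule`` picks the smallness criterion: ``"observed"``
    (any observed cell < 5, the reconstruction of the study's practice)
    or ``"expected"`` (any expected cell < 5).  Returns ``(p, test_name)``.
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if np.any(t != np.round(t)) or np.any(t < 0):
            raise ValueError("table must hold nonnegative integer counts")
        t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    if t.shape == (2, 2):
        expected = sps.contingency.expected_freq(t)
        small = (t < 5).any() if rule == "observed" else (expected < 5).any()
        if small:
            return float(sps.fisher_exact(t)[1]), "fisher"
    chi2 = sps.chi2_contingency(t, correction=False)
    return float(chi2.pvalue), "chi2"


def univariate_regression(y, x, variable: str = "") -> RegressionResult:
    """Ordinary least squares of ``y`` on one predictor ``x``.

    Reports the raw slope and its standard error, the standardized
    coefficient (slope * sd(x)/sd(y), which equals the Pearson r in the
    univariate case), R², adjusted r² = 1 - (1-R²)(n-1)/(n-2), and the
    two-sided p-value of the slope.  Rows with missing values are dropped
    pairwise.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have the same length")
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    n = y.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope is not identifiable")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    sy = y.std(ddof=1)
    beta_std = float(res.slope * x.std(ddof=1) / sy) if sy > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        n=n,
        beta_std=beta_std,
        slope_raw=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r2=r2,
        adj_r2=float(adj),
        p_value=float(res.pvalue),
    )


def icc_two_way_average(
    ratings, alpha: float = 0.05, agreement: bool = True
) -> IccResult:
    """ICC(2,k): two-way random-effects, average-measures reliability.

    ``ratings`` is an ``n_targets x k_raters`` complete matrix.  With
    ``agreement`` (default) the absolute-agreement form is computed from
    the two-way ANOVA mean squares,

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n),

    with the F-based confidence interval of McGraw & Wong; with
    ``agreement=False`` the consistency form (MSR - MSE)/MSR is used.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 targets and >= 2 raters")
    if not np.isfinite(X).all():
        raise ValueError("ratings matrix must be complete (no missing cells)")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    # interaction residuals directly: exactly zero for identical raters
    resid = X - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    msr = ss_rows / (n - 1)          # between targets
    msc = ss_cols / (k - 1)          # between raters
    mse = ss_err / ((n - 1) * (k - 1))

    if not agreement:
        if msr == 0:
            return IccResult(icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                             model="two_way_random_average_consistency")
        icc = (msr - mse) / msr
        f = msr / mse if mse > 0 else np.inf
        fl = f / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = f * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        return IccResult(icc=float(icc), ci_low=float(1 - 1 / fl),
                         ci_high=float(1 - 1 / fu),
                         model="two_way_random_average_consistency")

    denom = msr + (msc - mse) / n
    if denom == 0:
        return IccResult(icc=np.nan, ci_low=np.nan, ci_high=np.nan)
    icc_k = (msr - mse) / denom

    # single-measures absolute agreement and its CI (McGraw & Wong), then
    # the Spearman-Brown step up to average measures
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if (mse == 0 and msc == 0) or icc_1 >= 1.0 - 1e-12:
        # degenerate ratings (raters numerically identical): zero-width CI
        return IccResult(icc=float(icc_k), ci_low=float(icc_k), ci_high=float(icc_k))
    a = k * icc_1 / (n * (1 - icc_1))
    b = 1 + k * icc_1 * (n - 1) / (n * (1 - icc_1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi1 = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    lo_k = lo1 * k / (1 + lo1 * (k - 1))
    hi_k = hi1 * k / (1 + hi1 * (k - 1))
    return IccResult(icc=float(icc_k), ci_low=float(lo_k), ci_high=float(hi_k))
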