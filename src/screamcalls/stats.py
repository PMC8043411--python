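"""Shared statistical machinery.

Implements the handful of inferential tools the scream-call analyses rely
on: a one-way repeated-measures ANOVA with Mauchly's sphericity test and a
Greenhouse-Geisser correction applied conditionally, the paired t test,
Benjamini-Hochberg FDR adjustment, Pearson correlation, ordinary least
squares with an overall F test, and the inverse standard-normal quantile
used by the d-prime computation.

The repeated-measures ANOVA is written out explicitly rather than delegated
because its contract here is specific: the correction is applied only when
Mauchly's test rejects sphericity at p < 0.05, the effect size is partial
eta-squared, and the k = 2 design must reduce exactly to the squared paired
t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "RegressionResult",
    "rm_anova",
    "paired_t",
    "fdr_adjust",
    "pearson",
    "ols",
    "z_quantile",
]


@dataclass(frozen=True)
class AnovaResult:
    """Result of a one-way repeated-measures ANOVA.

    ``df_num``/``df_den`` are the degrees of freedom actually used for the
    reported p-value; they are non-integer when the Greenhouse-Geisser
    correction was applied. ``epsilon`` is always reported, ``corrected``
    says whether it entered the p-value.
    """

    f_value: float
    df_num: float
    df_den: float
    p_value: float
    eta_sq: float
    epsilon: float
    mauchly_p: float | None
    corrected: bool

    def __post_init__(self) -> None:
        if self.f_value < 0:
            raise ValueError("F statistic must be nonnegative")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: slope coefficients, intercept, overall F, R^2, p."""

    coefficients: np.ndarray
    intercept: float
    f_value: float
    r_squared: float
    p_value: float
    predictor_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("R^2 outside [0, 1]")


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to ones)."""
    return scipy.linalg.helmert(k, full=False)


def rm_anova(data: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a participants x levels matrix.

    Sphericity is assessed with Mauchly's test on orthonormal contrasts
    when k >= 3; if it rejects at p < 0.05 the Greenhouse-Geisser epsilon
    multiplies both degrees of freedom before the p-value is computed.
    Effect size is partial eta-squared, SS_effect / (SS_effect + SS_error).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2D participants x levels matrix")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    if k < 2:
        raise ValueError("need at least 2 levels")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells in data")

    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subject = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_effect = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_effect, 0.0)

    df1 = float(k - 1)
    df2 = float((n - 1) * (k - 1))
    ms_effect = ss_effect / df1
    ms_error = ss_error / df2

    scale = max(ss_total, 1.0)
    if ss_effect <= 1e-14 * scale:
        f_value = 0.0
    elif ms_error <= 1e-14 * scale:
        f_value = float("inf")
    else:
        f_value = ms_effect / ms_error
    eta_sq = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0

    # Sphericity handling on the covariance of orthonormal contrasts.
    epsilon = 1.0
    mauchly_p: float | None = None
    if k >= 3:
        cmat = _orthonormal_contrasts(k)
        cov = np.cov(x, rowvar=False, ddof=1)
        s = cmat @ cov @ cmat.T
        tr = float(np.trace(s))
        if tr > 1e-14 * scale:
            epsilon = tr**2 / ((k - 1) * float(np.trace(s @ s)))
            epsilon = float(np.clip(epsilon, 1.0 / (k - 1), 1.0))
            eig = np.linalg.eigvalsh(s)
            if np.all(eig > 0) and n - 1 >= k - 1:
                w = float(np.prod(eig) / (tr / (k - 1)) ** (k - 1))
                d = k - 1
                # chi-square approximation with the standard second-order
                # term of Mauchly's asymptotic expansion
                f_corr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
                w2 = (
                    (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
                    / (288.0 * ((n - 1) * d * f_corr) ** 2)
                )
                chi2 = -(n - 1) * f_corr * np.log(w)
                df_m = max(d * (d + 1) / 2.0 - 1.0, 1.0)
                p1 = scipy.stats.chi2.sf(chi2, df_m)
                p2 = scipy.stats.chi2.sf(chi2, df_m + 4)
                mauchly_p = float(p1 + w2 * (p2 - p1))
            else:
                # Singular contrast covariance: sphericity definitely violated.
                mauchly_p = 0.0

    corrected = mauchly_p is not None and mauchly_p < 0.05
    if corrected:
        df1_used, df2_used = epsilon * df1, epsilon * df2
    else:
        df1_used, df2_used = df1, df2

    if np.isinf(f_value):
        p_value = 0.0
    else:
        p_value = float(scipy.stats.f.sf(f_value, df1_used, df2_used))

    return AnovaResult(
        f_value=f_value,
        df_num=df1_used,
        df_den=df2_used,
        p_value=p_value,
        eta_sq=eta_sq,
        epsilon=epsilon,
        mauchly_p=mauchly_p,
        corrected=corrected,
    )


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    if np.var(diff, ddof=1) <= 0:
        raise ValueError("zero variance of paired differences")
    res = scipy.stats.ttest_rel(x, y)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise ValueError("zero variance input")
    res = scipy.stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def ols(
    design: np.ndarray,
    y: np.ndarray,
    predictor_names: tuple[str, ...] | None = None,
) -> RegressionResult:
    """OLS of y on the columns of ``design`` plus an intercept.

    The F statistic tests the full model against the intercept-only model.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match design rows")
    if n <= p + 1:
        raise ValueError("need more observations than parameters")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < p + 1:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, Xc).fit()
    f_value = float(fit.fvalue)
    p_value = float(fit.f_pvalue)
    if not np.isfinite(f_value):  # perfect fit: F -> infinity
        f_value, p_value = float("inf"), 0.0
    names = tuple(predictor_names) if predictor_names is not None else tuple(
        f"x{i}" for i in range(p)
    )
    return RegressionResult(
        coefficients=np.asarray(fit.params[1:]),
        intercept=float(fit.params[0]),
        f_value=f_value,
        r_squared=float(fit.rsquared),
        p_value=p_value,
        predictor_names=names,
    )


def z_quantile(q: float) -> float:
    """Inverse standard-normal CDF, the Z transform used by d-prime."""
    if not 0.0 < q < 1.0:
        raise ValueError("quantile argument must lie strictly in (0, 1)")
    return float(scipy.stats.norm.ppf(q))
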