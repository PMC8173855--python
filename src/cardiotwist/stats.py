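"""Cohort statistics: z-scoring, PCA, normality-routed group tests,
regression, and observer agreement.

Group comparisons are routed by a Lilliefors normality test on each group
(alpha = 0.05): if both groups are compatible with normality an unpaired
two-tailed Student t-test (pooled variance) is used, otherwise the
Mann-Whitney rank-sum test.  PCA operates on the z-scored metric matrix
(i.e. the correlation structure) with a deterministic sign convention.
Observer agreement uses the two-way absolute-agreement single-measure
intraclass correlation ICC(A,1) and Bland-Altman differences with the 95%
confidence interval of the mean difference (reported alongside the limits
of agreement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import DomainError

__all__ = [
    "PCAResult",
    "AgreementResult",
    "GroupComparison",
    "RegressionResult",
    "zscore",
    "pca",
    "normality_route",
    "compare_groups",
    "univariate_regression",
    "icc",
    "bland_altman",
    "benjamini_hochberg",
]

META_COLUMNS = ("subject_id", "group", "species")


def _metric_columns(table: pd.DataFrame, columns: Optional[Sequence[str]]) -> list:
    if columns is not None:
        return list(columns)
    return [c for c in table.columns if c not in META_COLUMNS and pd.api.types.is_numeric_dtype(table[c])]


def zscore(table: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Z-score each metric column over the combined table (all groups pooled)."""
    cols = _metric_columns(table, columns)
    if len(table) < 2:
        raise DomainError("z-scoring needs at least 2 subjects (SD undefined)")
    out = table.copy()
    for c in cols:
        sd = float(table[c].std(ddof=1))
        if sd <= 0 or not np.isfinite(sd):
            raise DomainError(f"zero or undefined SD in column {c!r}")
        out[c] = (table[c] - table[c].mean()) / sd
    return out


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (p, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    k: int
    metrics: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise DomainError("loadings columns must be orthonormal")
        if np.any(np.diff(self.explained_variance_ratio) > 1e-12):
            raise DomainError("explained-variance fractions must be non-increasing")
        if self.explained_variance_ratio.sum() > 1.0 + 1e-9:
            raise DomainError("explained-variance fractions must sum to <= 1")


def pca(table: pd.DataFrame, k: int = 3, columns: Optional[Sequence[str]] = None) -> PCAResult:
    """PCA of the z-scored metric matrix via SVD.

    Sign convention: within each component the largest-magnitude loading
    is made positive, so results are deterministic across BLAS builds.
    ``k`` must satisfy 1 <= k <= min(n - 1, p).
    """
    cols = _metric_columns(table, columns)
    X = zscore(table, cols)[cols].to_numpy(dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise DomainError(f"k={k} out of range for {n} subjects x {p} metrics")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = (S**2) / np.sum(S**2)
    loadings = Vt.T[:, :k].copy()
    scores = (U * S)[:, :k].copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr[:k],
        k=k,
        metrics=tuple(cols),
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    route: str  # "ttest" or "mannwhitney"
    normal: Tuple[bool, bool] = (True, True)


def _check_group(x: np.ndarray, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DomainError(f"group {label} needs n >= 3")
    return x


def normality_route(a: Iterable[float], b: Iterable[float], alpha: float = 0.05) -> str:
    """Choose the two-group test: t-test if both groups pass Lilliefors, else Mann-Whitney."""
    a = _check_group(np.fromiter(a, float), "a")
    b = _check_group(np.fromiter(b, float), "b")
    normal = []
    for x in (a, b):
        if np.ptp(x) < 1e-12:
            normal.append(True)  # degenerate but not evidence against normality
            continue
        _, p = _lilliefors(x, dist="norm")
        normal.append(p > alpha)
    return "ttest" if all(normal) else "mannwhitney"


def compare_groups(
    a: Iterable[float],
    b: Iterable[float],
    route: str = "auto",
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Two-group comparison with normality routing.

    ``route`` is ``"auto"`` (Lilliefors-routed), ``"ttest"`` or
    ``"mannwhitney"``.  The t-test is the classical pooled-variance
    Student form unless ``welch=True``.
    """
    a = _check_group(np.fromiter(a, float), "a")
    b = _check_group(np.fromiter(b, float), "b")
    if route == "auto":
        route = normality_route(a, b, alpha)
    if route == "ttest":
        if np.ptp(a) < 1e-12 and np.ptp(b) < 1e-12 and a.mean() == b.mean():
            return GroupComparison(statistic=0.0, p_value=1.0, route="ttest")
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    elif route == "mannwhitney":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise DomainError(f"unknown route {route!r}")
    return GroupComparison(statistic=float(stat), p_value=float(p), route=route)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    stderr: float


def univariate_regression(x: Iterable[float], y: Iterable[float]) -> RegressionResult:
    """Ordinary least squares of y on x with Pearson r and two-sided slope p."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("regression needs n >= 3 paired observations")
    if np.ptp(x) < 1e-12:
        raise DomainError("x is constant: slope undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


# ---------------------------------------------------------------------------
# observer agreement


@dataclass
class AgreementResult:
    """ICC and/or Bland-Altman summary of paired observer measurements."""

    n: int
    icc: Optional[float] = None
    mean_difference: Optional[float] = None
    sd_difference: Optional[float] = None
    ci_lower: Optional[float] = None  # 95% CI of the mean difference
    ci_upper: Optional[float] = None
    loa_lower: Optional[float] = None  # 95% limits of agreement
    loa_upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.icc is not None and self.icc > 1.0 + 1e-12:
            raise DomainError("ICC cannot exceed 1")
        if self.ci_lower is not None and not (
            self.ci_lower - 1e-12 <= self.mean_difference <= self.ci_upper + 1e-12
        ):
            raise DomainError("mean difference must lie inside its confidence interval")


def _paired(r1: Iterable[float], r2: Iterable[float]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(list(r1), dtype=float)
    y = np.asarray(list(r2), dtype=float)
    if x.size != y.size:
        raise DomainError("raters must supply equal-length paired measurements")
    if x.size < 3:
        raise DomainError("agreement analysis needs n >= 3 pairs")
    return x, y


def icc(rater1: Iterable[float], rater2: Iterable[float]) -> AgreementResult:
    """Two-way absolute-agreement single-measure intraclass correlation ICC(A,1).

    Computed from the two-way ANOVA mean squares:
        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    with n subjects and k = 2 raters.
    """
    x, y = _paired(rater1, rater2)
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = 1.0 if abs(denom) < 1e-30 else (msr - mse) / denom
    return AgreementResult(n=n, icc=float(min(value, 1.0)))


def bland_altman(rater1: Iterable[float], rater2: Iterable[float]) -> AgreementResult:
    """Bland-Altman paired differences (rater1 - rater2).

    Reports the mean difference with its 95% confidence interval (t-based;
    the primary agreement summary) and the 95% limits of agreement
    (mean +/- 1.96 SD).
    """
    x, y = _paired(rater1, rater2)
    d = x - y
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return AgreementResult(
        n=n,
        mean_difference=mean,
        sd_difference=sd,
        ci_lower=mean - half,
        ci_upper=mean + half,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; no correction is applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out


def group_comparison_report(
    table: pd.DataFrame,
    pairs: Sequence[Tuple[str, str]] = (("control", "pah"), ("sham", "pab")),
    columns: Optional[Sequence[str]] = None,
    route: str = "auto",
) -> pd.DataFrame:
    """Per-metric two-group comparisons for the named group pairs."""
    cols = _metric_columns(table, columns)
    rows = []
    for g1, g2 in pairs:
        a = table[table["group"] == g1]
        b = table[table["group"] == g2]
        if a.empty or b.empty:
            raise DomainError(f"missing group in pair ({g1}, {g2})")
        for c in cols:
            cmp_ = compare_groups(a[c], b[c], route=route)
            rows.append(
                {
                    "metric": c,
                    "group_a": g1,
                    "group_b": g2,
                    "route": cmp_.route,
                    "statistic": cmp_.statistic,
                    "p_value": cmp_.p_value,
                }
            )
    return pd.DataFrame(rows)
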