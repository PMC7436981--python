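"""Reliability (ICC, SEM) and convergent-validity correlation analyses.

Relative reliability uses the two-way random-effects, absolute-agreement,
average-of-k-measures intraclass correlation, ICC(2,k) — with k = 3 for the
three LoS repetitions per height level.  From the two-way ANOVA mean squares
(rows = subjects, columns = trials):

    ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

Absolute reliability is the standard error of measurement,
``SEM = SD x sqrt(1 - ICC)`` with SD the pooled standard deviation of all
observations, and its percent-of-mean form ``%SEM = SEM / grand mean x 100``.

Interpretation bands: ICC < 0.40 poor, 0.40-<0.75 acceptable, >=0.75 high;
%SEM > 20 poor, 10-20 acceptable, <=10 high.  Correlation strength on |r|:
0.00-0.19 negligible, 0.20-0.34 weak, 0.35-0.50 moderate, > 0.50 strong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "ReliabilityReport",
    "CorrelationReport",
    "icc_2k",
    "sem_from_icc",
    "reliability_report",
    "correlate",
    "collinearity_screen",
    "icc_label",
    "sem_pct_label",
    "correlation_label",
]


def icc_label(icc: float) -> str:
    if icc < 0.40:
        return "poor"
    if icc < 0.75:
        return "acceptable"
    return "high"


def sem_pct_label(sem_pct: float) -> str:
    if sem_pct > 20.0:
        return "poor"
    if sem_pct > 10.0:
        return "acceptable"
    return "high"


def correlation_label(r: float) -> str:
    a = abs(r)
    if a < 0.20:
        return "negligible"
    if a < 0.35:
        return "weak"
    if a <= 0.50:
        return "moderate"
    return "strong"


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    icc_ci95: tuple[float, float]
    sem: float
    sem_pct: float
    relative_label: str
    absolute_label: str
    n_subjects: int
    k_trials: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationReport:
    method: str
    r: float
    r_squared: float
    p_value: float
    strength_label: str
    n: int
    degenerate: bool = False


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of a complete two-way layout, one obs/cell."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2k(table, ci: float = 0.95) -> tuple[float, tuple[float, float], bool]:
    """ICC(2,k) point estimate and F-based confidence interval.

    ``table`` is an (n_subjects x k_trials) array with no missing cells.
    Returns ``(icc, (lo, hi), degenerate)``; ``degenerate`` is True when the
    table has no variance at all, in which case the ICC is undefined (NaN).

    The CI follows the standard two-way random-effects construction: an
    F-based interval for the single-measure ICC(2,1), stepped up to average
    measures with the Spearman-Brown relation.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise DataError(f"reliability table must be 2-D, got shape {table.shape}")
    n, k = table.shape
    if n < 2 or k < 2:
        raise DataError(f"need at least 2 subjects and 2 trials, got {n} x {k}")
    if not np.all(np.isfinite(table)):
        raise DataError("reliability table contains missing or non-finite cells")
    if np.allclose(table, table.flat[0]):
        return math.nan, (math.nan, math.nan), True

    msr, msc, mse = _two_way_mean_squares(table)
    denom = msr + (msc - mse) / n
    icc_k = math.nan if denom == 0 else (msr - mse) / denom

    # single-measure ICC(2,1) and its F interval (then Spearman-Brown step-up)
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    alpha = 1.0 - ci
    if mse > 0:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
        vd = (n - 1) * k**2 * icc_1**2 * fj**2 + (n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
        v = vn / vd
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        lo = k * lo1 / (1 + (k - 1) * lo1)
        hi = k * hi1 / (1 + (k - 1) * hi1)
    else:
        lo, hi = icc_k, icc_k  # no residual variance: estimate is exact
    lo = min(lo, icc_k)
    hi = max(hi, icc_k)
    return float(icc_k), (float(lo), float(hi)), False


def sem_from_icc(table, icc: float, use_ms_error: bool = False) -> tuple[float, float]:
    """Standard error of measurement and its percent-of-mean form.

    Default: ``SEM = SD_pooled x sqrt(1 - ICC)`` with the pooled SD of all
    observations.  ``use_ms_error=True`` switches to ``SEM = sqrt(MS_error)``.
    %SEM is flagged undefined (NaN) when the grand mean is zero.
    """
    table = np.asarray(table, dtype=float)
    if use_ms_error:
        _, _, mse = _two_way_mean_squares(table)
        sem = math.sqrt(max(mse, 0.0))
    else:
        sd = float(np.std(table, ddof=1))
        sem = sd * math.sqrt(max(1.0 - icc, 0.0))
    grand = float(table.mean())
    sem_pct = math.nan if grand == 0 else sem / grand * 100.0
    return sem, sem_pct


def reliability_report(table, ci: float = 0.95, use_ms_error: bool = False) -> ReliabilityReport:
    """ICC(2,k), SEM, %SEM and their interpretation labels for one measure."""
    table = np.asarray(table, dtype=float)
    icc, icc_ci, degenerate = icc_2k(table, ci=ci)
    if degenerate:
        sem, sem_pct = 0.0, 0.0
        rel_label = abs_label = "high"
    else:
        sem, sem_pct = sem_from_icc(table, icc, use_ms_error=use_ms_error)
        rel_label = icc_label(icc)
        abs_label = sem_pct_label(sem_pct) if math.isfinite(sem_pct) else "undefined"
    n, k = table.shape
    return ReliabilityReport(
        icc=icc,
        icc_ci95=icc_ci,
        sem=sem,
        sem_pct=sem_pct,
        relative_label=rel_label,
        absolute_label=abs_label,
        n_subjects=n,
        k_trials=k,
        degenerate=degenerate,
    )


def correlate(x, y, method: str = "auto", alpha: float = 0.05) -> CorrelationReport:
    """Pearson or Spearman correlation with the interpretation bands.

    ``method='auto'`` runs a Shapiro-Wilk normality gate on each variable and
    falls back to Spearman when either rejects at the given alpha — Pearson
    for jointly plausible-normal data, ranks otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DataError(f"need at least 3 observations, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationReport(
            method=method, r=math.nan, r_squared=math.nan, p_value=math.nan,
            strength_label="undefined", n=int(x.size), degenerate=True,
        )
    if method == "auto":
        method = "pearson"
        if stats.shapiro(x).pvalue <= alpha or stats.shapiro(y).pvalue <= alpha:
            method = "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise DataError(f"unknown correlation method {method!r}")
    r = float(r)
    return CorrelationReport(
        method=method,
        r=r,
        r_squared=r * r,
        p_value=float(p),
        strength_label=correlation_label(r),
        n=int(x.size),
    )


def collinearity_screen(features, names: Optional[list[str]] = None, threshold: float = 0.80):
    """Flag predictor pairs with Pearson |r| strictly above the threshold.

    ``features`` is an (n x p) array or DataFrame; returns a list of
    ``(name_i, name_j, r)`` tuples for every flagged pair.
    """
    import pandas as pd

    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        mat = features.to_numpy(dtype=float)
    else:
        mat = np.asarray(features, dtype=float)
        if names is None:
            names = [f"x{i}" for i in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise DataError("collinearity screen needs at least 2 feature columns")
    corr = np.corrcoef(mat, rowvar=False)
    flagged = []
    for i, j in combinations(range(mat.shape[1]), 2):
        r = float(corr[i, j])
        if abs(r) > threshold:
            flagged.append((names[i], names[j], r))
    return flagged
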