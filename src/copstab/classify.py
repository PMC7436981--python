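"""Fear-of-falling classification from CoP dwell indices.

Participants are dichotomised by the FES-I questionnaire (16-22 low FoF,
23-64 high FoF; high is the positive class throughout).  Each candidate CoP
index is evaluated as a single-predictor binary logistic model, with:

* odds ratio and Wald 95 % CI for the predictor;
* ROC analysis — AUC via the rank (Mann-Whitney) formulation with midrank tie
  handling, a seeded stratified-bootstrap CI, and automatic orientation so
  that AUC >= 0.5 (an index may mark the positive class by *low* values, as
  FTR_1/2 does);
* the Youden-optimal cutoff J = sensitivity + specificity - 1, reported at an
  observed score value with inclusive orientation ("<= c" / ">= c");
* corrected AIC for model comparison (lowest wins) — 'aicc' (small-sample
  AICc, the default) or 'consistent' (Bozdogan's CAIC);
* stratified fivefold cross-validation with per-fold refitting of both the
  logistic model and the cutoff.

The published decision rule for the ratio index at ground level is
"high FoF iff FTR_1/2 <= 2.83" (<= 2.71 for the 40-cm height condition);
:func:`apply_threshold` implements that rule for arbitrary cutoffs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import DataError
from .io import fesi_group  # noqa: F401  (canonical grouping lives with SubjectRecord)

__all__ = [
    "LogisticFit",
    "RocResult",
    "CvResult",
    "ModelReport",
    "fesi_group",
    "fit_logistic",
    "roc_analysis",
    "youden_cutoff",
    "caic",
    "crossvalidate",
    "apply_threshold",
    "classifier_report",
    "GROUND_CUTOFF",
    "H40CM_CUTOFF",
]

#: published FTR_1/2 decision cutoffs (high FoF iff value <= cutoff)
GROUND_CUTOFF = 2.83
H40CM_CUTOFF = 2.71


@dataclass(frozen=True)
class LogisticFit:
    beta0: float
    beta1: float
    odds_ratio: float
    or_ci95: tuple[float, float]
    p_value: float
    log_likelihood: float
    n: int
    converged: bool
    separated: bool = False


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray  # observed score values (original units)
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    orientation: str  # 'higher_is_positive' | 'lower_is_positive'
    youden_cutoff: float
    youden_sens: float
    youden_spec: float
    #: decision boundary for *new* data: midway between the Youden-optimal
    #: observed value and the next observed score.  The observed-value cutoff
    #: is a reporting convention; used verbatim on held-out data it sits on a
    #: training observation and misclassifies any new case just beyond it.
    youden_cutoff_midpoint: float = math.nan
    degenerate: bool = False


@dataclass(frozen=True)
class CvResult:
    folds: int
    error_pct: float
    sensitivity_pct: float
    specificity_pct: float
    seed: int
    confusion: tuple[int, int, int, int]  # tp, fp, tn, fn


@dataclass(frozen=True)
class ModelReport:
    """Everything reported for one candidate predictor (Table-4 style)."""

    name: str
    fit: LogisticFit
    roc: RocResult
    caic: float
    accuracy_pct: float
    cv: Optional[CvResult]


def _as_binary(labels) -> np.ndarray:
    """Map labels to {0, 1} with 'high' / 1 / True as the positive class."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        y = np.asarray([1 if str(v) == "high" else 0 for v in arr])
    else:
        y = arr.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise DataError(f"labels must be binary, got values {np.unique(arr)}")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present")
    return y


def fit_logistic(x, y) -> LogisticFit:
    """Maximum-likelihood single-predictor logistic regression.

    Newton iterations to 1e-8 on the log-likelihood (at most 100), via
    statsmodels.  Complete separation is detected up front (a univariate
    predictor separates iff the class score ranges do not overlap) and
    returned as a flagged result — infinite odds-ratio CI, ``converged=False``
    — rather than an exception.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(x, dtype=float)
    yb = _as_binary(y)
    if x.shape != yb.shape:
        raise DataError(f"x and y lengths differ: {x.shape} vs {yb.shape}")
    n = int(x.size)

    if x[yb == 0].max() < x[yb == 1].min() or x[yb == 1].max() < x[yb == 0].min():
        sign = 1.0 if x[yb == 1].min() > x[yb == 0].max() else -1.0
        return LogisticFit(
            beta0=math.nan, beta1=sign * math.inf,
            odds_ratio=math.inf if sign > 0 else 0.0,
            or_ci95=(0.0, math.inf), p_value=math.nan,
            log_likelihood=0.0, n=n, converged=False, separated=True,
        )

    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(yb, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(
            beta0=math.nan, beta1=math.nan, odds_ratio=math.nan,
            or_ci95=(0.0, math.inf), p_value=math.nan,
            log_likelihood=0.0, n=n, converged=False, separated=True,
        )
    beta0, beta1 = map(float, res.params)
    se1 = float(res.bse[1])
    lo, hi = math.exp(beta1 - 1.959963984540054 * se1), math.exp(beta1 + 1.959963984540054 * se1)
    return LogisticFit(
        beta0=beta0,
        beta1=beta1,
        odds_ratio=math.exp(beta1),
        or_ci95=(lo, hi),
        p_value=float(res.pvalues[1]),
        log_likelihood=float(res.llf),
        n=n,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie correction (higher = positive)."""
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(scores)
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _curve(scores_oriented: np.ndarray, y: np.ndarray):
    """Sens/spec at every observed oriented threshold (predicate s >= thr)."""
    thr = np.unique(scores_oriented)[::-1]  # descending: strictest first
    pos = scores_oriented[y == 1]
    neg = scores_oriented[y == 0]
    sens = np.array([(pos >= c).mean() for c in thr])
    spec = np.array([(neg < c).mean() for c in thr])
    # prepend the predict-nothing endpoint, append nothing (last thr = predict all)
    thr = np.concatenate([[np.inf], thr])
    sens = np.concatenate([[0.0], sens])
    spec = np.concatenate([[1.0], spec])
    return thr, sens, spec


def roc_analysis(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve, AUC with bootstrap CI, and the Youden-optimal cutoff.

    Orientation is chosen so the reported AUC is >= 0.5: when low scores mark
    the positive class the result carries ``orientation='lower_is_positive'``
    and cutoffs are read as "positive iff score <= cutoff".  The AUC CI is a
    percentile interval over ``n_boot`` class-stratified bootstrap resamples.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise DataError(f"scores and labels lengths differ: {s.shape} vs {y.shape}")

    degenerate = np.unique(s).size == 1
    auc_high = 0.5 if degenerate else _rank_auc(s, y)
    if auc_high >= 0.5:
        orientation, s_or = "higher_is_positive", s
        auc = auc_high
    else:
        orientation, s_or = "lower_is_positive", -s
        auc = _rank_auc(-s, y)

    thr_or, sens, spec = _curve(s_or, y)
    thresholds = thr_or if orientation == "higher_is_positive" else -thr_or

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos_idx, pos_idx.size), rng.choice(neg_idx, neg_idx.size)]
        )
        sb, yb = s_or[idx], y[idx]
        boot[b] = 0.5 if np.unique(sb).size == 1 else _rank_auc(sb, yb)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    cut, ysens, yspec, cut_mid = _youden_from_curve(thr_or, sens, spec, thresholds)
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
        auc_ci95=ci,
        orientation=orientation,
        youden_cutoff=cut,
        youden_sens=ysens,
        youden_spec=yspec,
        youden_cutoff_midpoint=cut_mid,
        degenerate=degenerate,
    )


def _youden_from_curve(thr_or, sens, spec, thresholds_orig):
    """Best observed cutoff by J; ties -> higher sens, then more extreme cutoff.

    Also returns the midpoint decision boundary: halfway to the next observed
    threshold (the training confusion matrix is identical anywhere in that
    gap, and the midpoint generalises symmetrically).
    """
    j = sens + spec - 1.0
    finite = np.isfinite(thr_or)
    best = None
    for i in np.flatnonzero(finite):
        key = (j[i], sens[i], thr_or[i])  # larger oriented thr = more extreme
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    if i + 1 < thresholds_orig.size:
        midpoint = 0.5 * (thresholds_orig[i] + thresholds_orig[i + 1])
    else:
        midpoint = thresholds_orig[i]
    return float(thresholds_orig[i]), float(sens[i]), float(spec[i]), float(midpoint)


def youden_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) at the Youden-optimal threshold."""
    return roc.youden_cutoff, roc.youden_sens, roc.youden_spec


def caic(log_likelihood: float, k_params: int, n: int, variant: str = "aicc") -> float:
    """Corrected AIC of a fitted model (lower is better).

    ``variant='aicc'``: -2 lnL + 2k + 2k(k+1)/(n-k-1) (small-sample AIC);
    ``variant='consistent'``: -2 lnL + k(ln n + 1) (Bozdogan).
    """
    if variant == "aicc":
        if n <= k_params + 1:
            raise DataError(f"AICc needs n > k+1, got n={n}, k={k_params}")
        return -2.0 * log_likelihood + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)
    if variant == "consistent":
        return -2.0 * log_likelihood + k_params * (math.log(n) + 1.0)
    raise DataError(f"unknown CAIC variant {variant!r}")


def apply_threshold(
    value: float,
    cutoff: float = GROUND_CUTOFF,
    orientation: str = "lower_is_positive",
) -> str:
    """Fixed-cutoff decision rule: returns ``'high'`` or ``'low'`` FoF.

    With the default orientation the rule is "high iff value <= cutoff"
    (inclusive), matching the published "<= 2.83" form; an infinite ratio
    (no time in region 2) therefore maps to low.
    """
    if math.isnan(value):
        raise DataError("cannot classify a NaN score")
    if orientation == "lower_is_positive":
        return "high" if value <= cutoff else "low"
    if orientation == "higher_is_positive":
        return "high" if value >= cutoff else "low"
    raise DataError(f"unknown orientation {orientation!r}")


def crossvalidate(
    scores,
    labels,
    folds: int = 5,
    seed: int = 0,
    reuse_global_cutoff: bool = False,
) -> CvResult:
    """Stratified k-fold cross-validation of the cutoff classifier.

    Per fold, a logistic model and the Youden cutoff are derived from the
    training split only and applied to the held-out fold; the pooled
    confusion matrix yields error, sensitivity and specificity (percent).
    Held-out prediction uses the midpoint decision boundary (see
    :class:`RocResult`), which leaves the training confusion matrix unchanged
    but does not sit exactly on a training observation.
    ``reuse_global_cutoff=True`` instead freezes the full-sample cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise DataError(
            f"each class needs >= {folds} members for {folds}-fold CV, got {counts.tolist()}"
        )
    if reuse_global_cutoff:
        global_roc = roc_analysis(s, y, n_boot=1, seed=seed)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for train, test in skf.split(s.reshape(-1, 1), y):
        if reuse_global_cutoff:
            fold_roc = global_roc
        else:
            fold_roc = roc_analysis(s[train], y[train], n_boot=1, seed=seed)
            fit_logistic(s[train], y[train])  # per-fold model fit (monotone in s)
        boundary = fold_roc.youden_cutoff_midpoint
        if not math.isfinite(boundary):
            boundary = fold_roc.youden_cutoff
        for v, truth in zip(s[test], y[test]):
            pred = apply_threshold(v, boundary, fold_roc.orientation)
            pred_pos = pred == "high"
            if pred_pos and truth == 1:
                tp += 1
            elif pred_pos and truth == 0:
                fp += 1
            elif not pred_pos and truth == 0:
                tn += 1
            else:
                fn += 1
    n = tp + fp + tn + fn
    return CvResult(
        folds=folds,
        error_pct=100.0 * (fp + fn) / n,
        sensitivity_pct=100.0 * tp / (tp + fn),
        specificity_pct=100.0 * tn / (tn + fp),
        seed=seed,
        confusion=(tp, fp, tn, fn),
    )


def classifier_report(
    name: str,
    scores,
    labels,
    seed: int = 0,
    n_boot: int = 2000,
    caic_variant: str = "aicc",
    cv_folds: int = 5,
) -> ModelReport:
    """Full single-predictor evaluation: logistic fit, ROC/Youden, CAIC, CV.

    Overall accuracy is the training-set accuracy of the Youden cutoff;
    cross-validation is skipped (None) when a class is smaller than the fold
    count.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    fit = fit_logistic(s, y)
    roc = roc_analysis(s, y, n_boot=n_boot, seed=seed)
    value = caic(fit.log_likelihood, k_params=2, n=fit.n, variant=caic_variant)
    preds = np.array(
        [apply_threshold(v, roc.youden_cutoff, roc.orientation) == "high" for v in s]
    )
    accuracy = 100.0 * float(np.mean(preds == (y == 1)))
    cv = None
    if np.bincount(y, minlength=2).min() >= cv_folds:
        cv = crossvalidate(s, y, folds=cv_folds, seed=seed)
    return ModelReport(name=name, fit=fit, roc=roc, caic=value, accuracy_pct=accuracy, cv=cv)
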