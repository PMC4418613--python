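"""Model evaluation: LOOCV, ROC/AUC, DeLong comparison, ICC, sample size.

Discrimination of the fitted logistic models is measured on out-of-fold
probabilities from leave-one-out cross-validation, summarized by ROC
curves and the Mann-Whitney AUC, and compared between models with the
DeLong placement-value test for correlated AUCs.  Inter-rater agreement of
the shape features is quantified with the two-way random-effects,
absolute-agreement, single-rater intraclass correlation (ICC(A,1)), and
the number of subjects needed to establish a target correlation is given
by the Fisher-z approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import LogisticFit, backward_stepwise, logistic_fit

__all__ = [
    "ROCResult",
    "ICCResult",
    "DeLongComparison",
    "loocv_probabilities",
    "roc_auc",
    "delong_ci_and_compare",
    "icc_agreement",
    "sample_size_correlation",
    "banding",
]


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation

def loocv_probabilities(cohort: pd.DataFrame, model_variables: list[str],
                        selection_in_fold: bool = False,
                        p_enter: float = 0.05,
                        p_remove: float = 0.10) -> np.ndarray:
    """Out-of-fold probability of invasiveness for every subject.

    Each subject is scored by a model trained on the other n-1.  With
    ``selection_in_fold`` the backward-stepwise search is re-run inside
    every fold (the stricter protocol); otherwise the supplied variable
    list is refit as-is in each fold.  Separable folds keep the last
    stable IRLS iterate rather than failing, so perfectly separable
    features legitimately score near 0/1.
    """
    y = cohort["label"].to_numpy(int)
    n = len(cohort)
    if n < 10:
        raise ValueError(f"LOOCV needs n >= 10 subjects, got {n}")
    X = cohort[model_variables].astype(float).reset_index(drop=True)
    probs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        y_tr = y[keep]
        if y_tr.min() == y_tr.max():
            raise ValueError("single-class training fold in LOOCV")
        X_tr = X.loc[keep]
        if selection_in_fold:
            res = backward_stepwise(X_tr, y_tr, p_enter=p_enter,
                                    p_remove=p_remove,
                                    on_separation="keep")
            fit = res.fit
        else:
            fit = logistic_fit(X_tr, y_tr, on_separation="keep")
        if fit.variables:
            probs[i] = fit.predict(X.iloc[[i]])[0]
        else:
            probs[i] = y_tr.mean()
    return probs


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)   # one per positive
    v01 = cmp.mean(axis=0)   # one per negative
    return v10, v01, m, n


def roc_auc(scores, labels, level: float = 0.95) -> ROCResult:
    """ROC curve and Mann-Whitney AUC (ties count 1/2).

    The curve sweeps thresholds over the unique scores with the
    convention "score >= threshold predicts invasive"; the AUC confidence
    interval is the DeLong normal-approximation interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    if labels.min() == labels.max():
        raise ValueError("ROC needs both classes present")
    v10, v01, m, n = _placements(scores, labels)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    tpr = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[labels == 0] >= t).mean() for t in thresholds])
    return ROCResult(auc=auc, ci_low=max(0.0, auc - half),
                     ci_high=min(1.0, auc + half),
                     fpr=fpr, tpr=tpr, thresholds=thresholds,
                     scores=scores, labels=labels)


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float
    delta_ci_low: float
    delta_ci_high: float


def delong_ci_and_compare(scores_a, scores_b, labels,
                          level: float = 0.95) -> DeLongComparison:
    """DeLong test for two correlated AUCs measured on the same subjects.

    Placement-value variance/covariance estimator; two-sided z-test for
    the AUC difference with its normal-approximation interval.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired scores must have identical length")
    v10a, v01a, m, n = _placements(scores_a, labels)
    v10b, v01b, _, _ = _placements(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_a, var_b, cov_ab = float(s[0, 0]), float(s[1, 1]), float(s[0, 1])
    var_delta = max(var_a + var_b - 2 * cov_ab, 0.0)
    delta = auc_a - auc_b
    if var_delta <= 0:
        z_stat, p = 0.0, 1.0
    else:
        z_stat = delta / math.sqrt(var_delta)
        p = float(2 * sps.norm.sf(abs(z_stat)))
    zq = sps.norm.ppf(0.5 + level / 2)
    half = zq * math.sqrt(var_delta)
    return DeLongComparison(
        auc_a=auc_a, auc_b=auc_b, delta=delta, var_a=var_a, var_b=var_b,
        cov_ab=cov_ab, z=z_stat, p=p,
        delta_ci_low=delta - half, delta_ci_high=delta + half)


# ---------------------------------------------------------------------------
# Intraclass correlation (agreement)

def banding(icc: float) -> str:
    """Agreement category: <=0.40 poor, then moderate, good, >0.80 excellent."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc <= 0.40:
        return "poor"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "good"
    return "excellent"


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float
    n_subjects: int
    k_raters: int
    category: str
    flagged: bool = False


def icc_agreement(ratings, level: float = 0.95) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC.

    ``ratings`` is an n-subjects x k-raters array with no missing cells.
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n), with
    mean squares from the two-way ANOVA (rows = subjects, columns =
    raters); the confidence interval is the standard F-based
    (McGraw-Wong) interval.  Zero between-subject variance leaves the ICC
    undefined and is flagged.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters array")
    n, k = ratings.shape
    if n < 5 or k < 2:
        raise ValueError(f"need n >= 5 subjects and k >= 2 raters, "
                         f"got {n} x {k}")
    if np.isnan(ratings).any():
        raise ValueError("missing cells are not allowed (no imputation)")

    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((ratings - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-30 or denom <= 0:
        return ICCResult(icc=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"), msr=msr, msc=msc, mse=mse,
                         n_subjects=n, k_raters=k, category="undefined",
                         flagged=True)
    icc = (msr - mse) / denom

    if mse <= 1e-30 and msc <= 1e-30:
        lo = hi = icc  # perfect agreement: degenerate interval
    else:
        alpha = 1.0 - level
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if not np.isfinite(a):
            lo = hi = 1.0
        else:
            num_v = (a * msc + b * mse) ** 2
            den_v = (a * msc) ** 2 / (k - 1) + \
                (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num_v / den_v if den_v > 0 else 1.0
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     msr=msr, msc=msc, mse=mse, n_subjects=n, k_raters=k,
                     category=banding(min(icc, 1.0)))


# ---------------------------------------------------------------------------
# Sample size for establishing a correlation

def sample_size_correlation(rho0: float, alpha: float = 0.05,
                            power: float = 0.80, sided: str = "one",
                            max_n: int = 10 ** 6) -> int:
    """Subjects needed to establish a correlation of at least ``rho0``.

    Fisher-z approximation: n = ceil(((z_alpha + z_power)/atanh(rho0))^2
    + 3), with z_alpha one- or two-sided.  Result is floored at 4.
    """
    if not (0 < rho0 < 1):
        raise ValueError("rho0 must be in (0, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    z_a = sps.norm.ppf(1 - alpha) if sided == "one" \
        else sps.norm.ppf(1 - alpha / 2)
    z_p = sps.norm.ppf(power)
    n = math.ceil(((z_a + z_p) / math.atanh(rho0)) ** 2 + 3)
    if n > max_n:
        raise ValueError(f"required n={n} exceeds max_n={max_n} "
                         f"(rho0 too close to 0)")
    return max(n, 4)
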