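"""Univariate screening and multivariable logistic modeling.

The discrimination question is binary: encapsulated (label 0) versus
invasive (label 1) tumor.  Candidate covariates are screened one at a time
(chi-square or Fisher's exact test for binary factors, Student's t for
continuous ones), then modeled jointly by maximum-likelihood logistic
regression with backward stepwise selection driven by likelihood-ratio
tests.  Odds ratios and Wald confidence intervals are reported per
coefficient, and collinearity is checked with variance inflation factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "LogisticFit",
    "StepwiseResult",
    "SeparationError",
    "odds_ratio_wald",
    "association_test",
    "two_sample_t",
    "univariate_screen",
    "logistic_fit",
    "likelihood_ratio_test",
    "backward_stepwise",
    "vif",
]

Z975 = sps.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation detected during IRLS."""

    def __init__(self, variable: str, beta: float):
        self.variable = variable
        self.beta = beta
        super().__init__(
            f"quasi-complete separation: |standardized coefficient| for "
            f"'{variable}' exceeded 15 (reached {beta:.1f})"
        )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts of a binary factor against the binary class.

    Rows are the class in the order (invasive, encapsulated) and columns
    the factor in the order (present, absent), so the cross-product odds
    ratio (a*d)/(b*c) answers "does factor presence predict invasiveness".

    a: invasive with factor; b: invasive without; c: encapsulated with;
    d: encapsulated without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell count in {cells}")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")

    @classmethod
    def from_cohort(cls, factor: np.ndarray, label: np.ndarray
                    ) -> "ContingencyTable2x2":
        factor = np.asarray(factor).astype(int)
        label = np.asarray(label).astype(int)
        return cls(
            a=int(((label == 1) & (factor == 1)).sum()),
            b=int(((label == 1) & (factor == 0)).sum()),
            c=int(((label == 0) & (factor == 1)).sum()),
            d=int(((label == 0) & (factor == 0)).sum()),
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class OddsRatioResult:
    or_: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied


def odds_ratio_wald(t: ContingencyTable2x2,
                    level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio with the Wald log-scale interval.

    OR = (a d)/(b c); SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d);
    CI = exp(log OR +- z SE).  A zero cell triggers the Haldane-Anscombe
    0.5 correction (flagged in the result); an empty margin is an error.
    """
    arr = t.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("odds ratio undefined: empty margin in 2x2 table")
    corrected = False
    if (arr == 0).any():
        arr = arr + 0.5
        corrected = True
    a, b = arr[0]
    c, d = arr[1]
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    return OddsRatioResult(
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        log_or=log_or,
        se_log_or=se,
        corrected=corrected,
    )


def association_test(t: ContingencyTable2x2) -> tuple[float, float, str]:
    """Chi-square or Fisher's exact association test on a 2x2 table.

    Pearson's chi-square (no continuity correction) when every expected
    cell count is >= 5, otherwise Fisher's exact test two-sided by the
    point-probability rule.  Returns (statistic, p, test name); Fisher's
    statistic slot carries its conditional odds ratio.
    """
    arr = t.as_array()
    rowsum = arr.sum(axis=1, keepdims=True)
    colsum = arr.sum(axis=0, keepdims=True)
    if rowsum.min() == 0 or colsum.min() == 0:
        raise ValueError("degenerate 2x2 table: zero margin")
    expected = rowsum @ colsum / arr.sum()
    if expected.min() < 5:
        stat, p = sps.fisher_exact(arr, alternative="two-sided")
        return float(stat), float(p), "fisher"
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), float(p), "chi2"


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided Student's t-test (pooled variance; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2 for the t-test")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _is_binary(values: np.ndarray) -> bool:
    uniq = np.unique(values[~np.isnan(values)])
    return np.all(np.isin(uniq, (0, 1)))


def univariate_screen(cohort: pd.DataFrame,
                      variables: list[str]) -> pd.DataFrame:
    """Per-variable two-group comparison against the class label.

    Binary {0,1} covariates get the 2x2 association test; continuous ones
    the pooled t-test.  Constant covariates are flagged with p = 1.
    Returns one row per variable with the test used, statistic, p, and
    per-class summaries (counts n/N for binary, mean +- SD otherwise).
    """
    label = cohort["label"].to_numpy()
    rows = []
    for var in variables:
        if var not in cohort.columns:
            raise KeyError(f"variable '{var}' not in cohort")
        vals = pd.to_numeric(cohort[var], errors="raise").to_numpy(float)
        enc, inv = vals[label == 0], vals[label == 1]
        if np.unique(vals).size == 1:
            rows.append(dict(variable=var, kind="constant", test="none",
                             statistic=np.nan, p=1.0,
                             encapsulated="constant", invasive="constant",
                             flagged=True))
            continue
        if _is_binary(vals):
            table = ContingencyTable2x2.from_cohort(vals, label)
            stat, p, test = association_test(table)
            rows.append(dict(
                variable=var, kind="binary", test=test, statistic=stat, p=p,
                encapsulated=f"{int(enc.sum())}/{len(enc)}",
                invasive=f"{int(inv.sum())}/{len(inv)}",
                flagged=False))
        else:
            stat, p = two_sample_t(enc, inv)
            rows.append(dict(
                variable=var, kind="continuous", test="t", statistic=stat,
                p=p,
                encapsulated=f"{enc.mean():.3f} ± {enc.std(ddof=1):.3f}",
                invasive=f"{inv.mean():.3f} ± {inv.std(ddof=1):.3f}",
                flagged=False))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Logistic regression by IRLS


@dataclass
class LogisticFit:
    """A maximum-likelihood logistic regression fit.

    Coefficient vectors are indexed by ['intercept', *variables] on the
    original (unstandardized) covariate scale.
    """

    variables: list[str]
    coef: pd.Series
    se: pd.Series
    loglik: float
    fitted: np.ndarray
    converged: bool
    n_iter: int
    nobs: int
    separated: bool = False

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coef)

    @property
    def wald_ci(self) -> pd.DataFrame:
        lo = np.exp(self.coef - Z975 * self.se)
        hi = np.exp(self.coef + Z975 * self.se)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    @property
    def zvalues(self) -> pd.Series:
        return self.coef / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * sps.norm.sf(np.abs(self.zvalues)),
                         index=self.coef.index)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.coef["intercept"] + (
            X[self.variables].to_numpy(float) @
            self.coef[self.variables].to_numpy())
        return expit(eta)

    def summary_table(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "coef": self.coef, "se": self.se, "odds_ratio": self.odds_ratios,
        }).join(self.wald_ci)
        tab["p"] = self.pvalues
        return tab


def _irls(X: np.ndarray, y: np.ndarray, tol_score: float = 1e-8,
          tol_dev: float = 1e-10, max_iter: int = 100,
          separation_beta: float = 15.0):
    """IRLS for the Bernoulli-logit GLM on a standardized design.

    Returns (beta, cov, loglik, converged, separated, n_iter).  The
    log-likelihood is non-decreasing across iterations (guaranteed here by
    step-halving).  Separation is declared when any standardized
    coefficient exceeds ``separation_beta`` in magnitude; the last stable
    iterate is returned with the flag set.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eps = 1e-10

    def loglik(b):
        eta = X @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = loglik(beta)
    converged = False
    separated = False
    it = 0
    cov = None
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), eps, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix (rank-deficient design)"
            ) from exc
        # step-halving keeps the log-likelihood monotone
        new_beta = beta + step
        new_ll = loglik(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = loglik(new_beta)
            halvings += 1
        if np.max(np.abs(new_beta)) > separation_beta:
            separated = True
            beta, ll = new_beta, new_ll
            break
        d_dev = abs(2.0 * (new_ll - ll))
        beta, ll = new_beta, new_ll
        if np.max(np.abs(X.T @ (y - expit(X @ beta)))) \
                < tol_score or d_dev < tol_dev:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), eps, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(info)
    return beta, cov, ll, converged, separated, it


def logistic_fit(X: pd.DataFrame, y, on_separation: str = "raise"
                 ) -> LogisticFit:
    """Fit logit(P(invasive)) = b0 + X b by maximum likelihood.

    Continuous covariates are standardized internally for IRLS stability
    and coefficients back-transformed to the original scale.  Standard
    errors come from the observed information.  ``on_separation`` is
    ``raise`` (default) or ``keep`` (return the last stable iterate with
    the flag set, as cross-validation requires for separable folds).
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    consts = [c for c in X.columns if X[c].nunique() == 1]
    if consts:
        raise ValueError(f"constant columns in design: {consts}")
    if not np.all(np.isin(np.unique(y), (0, 1))):
        raise ValueError("y must be binary 0/1")

    names = list(X.columns)
    Xv = X.to_numpy()
    # standardize non-binary columns
    means = np.zeros(p)
    scales = np.ones(p)
    for j in range(p):
        col = Xv[:, j]
        if not _is_binary(col):
            means[j] = col.mean()
            scales[j] = col.std(ddof=0) or 1.0
    Z = (Xv - means) / scales
    design = np.column_stack([np.ones(n), Z])

    beta_z, cov_z, ll, converged, separated, n_iter = _irls(design, y)

    if separated:
        j = int(np.argmax(np.abs(beta_z[1:])))
        if on_separation == "raise":
            raise SeparationError(names[j], float(beta_z[1 + j]))
        warnings.warn(f"separation on '{names[j]}'; keeping last stable "
                      f"iterate", stacklevel=2)

    # back-transform: beta_x[j] = beta_z[j]/s_j;
    # intercept_x = intercept_z - sum beta_z[j] m_j / s_j
    T = np.eye(p + 1)
    T[0, 1:] = -means / scales
    T[np.arange(1, p + 1), np.arange(1, p + 1)] = 1.0 / scales
    beta_x = T @ beta_z
    cov_x = T @ cov_z @ T.T

    index = ["intercept", *names]
    fitted = expit(design @ beta_z)
    return LogisticFit(
        variables=names,
        coef=pd.Series(beta_x, index=index),
        se=pd.Series(np.sqrt(np.diag(cov_x)), index=index),
        loglik=ll,
        fitted=fitted,
        converged=converged,
        n_iter=n_iter,
        nobs=n,
        separated=separated,
    )


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit
                          ) -> tuple[float, int, float]:
    """LR = 2 (ll_full - ll_reduced); p from chi-square on the df gap."""
    if not set(reduced.variables) <= set(full.variables):
        raise ValueError("reduced model is not nested in the full model")
    df = len(full.variables) - len(reduced.variables)
    if df == 0:
        return 0.0, 0, 1.0
    lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return lr, df, float(sps.chi2.sf(lr, df))


@dataclass
class StepwiseResult:
    fit: LogisticFit
    trace: list[dict] = field(default_factory=list)
    p_enter: float = 0.05
    p_remove: float = 0.10
    intercept_only: bool = False

    @property
    def selected(self) -> list[str]:
        return self.fit.variables


def _fit_subset(X: pd.DataFrame, y, cols: list[str],
                on_separation: str) -> LogisticFit:
    if cols:
        return logistic_fit(X[cols], y, on_separation=on_separation)
    # intercept-only fit, closed form
    y = np.asarray(y, float)
    pbar = y.mean()
    pbar = min(max(pbar, 1e-12), 1 - 1e-12)
    b0 = math.log(pbar / (1 - pbar))
    ll = float(np.sum(y * b0 - np.logaddexp(0.0, b0)))
    se0 = math.sqrt(1.0 / (len(y) * pbar * (1 - pbar)))
    return LogisticFit(
        variables=[], coef=pd.Series([b0], index=["intercept"]),
        se=pd.Series([se0], index=["intercept"]), loglik=ll,
        fitted=np.full(len(y), y.mean()), converged=True, n_iter=0,
        nobs=len(y))


def backward_stepwise(X: pd.DataFrame, y, p_enter: float = 0.05,
                      p_remove: float = 0.10,
                      on_separation: str = "raise") -> StepwiseResult:
    """Backward stepwise selection by likelihood-ratio tests.

    Starts from the model with all candidate columns of ``X``; at each
    step removes the variable with the largest LRT p-value if it exceeds
    ``p_remove``, then allows an excluded variable back in if its LRT
    p-value is below ``p_enter``.  Ties break by column order, so the
    procedure is deterministic for a fixed design.  An empty candidate set
    yields the intercept-only fit, flagged.
    """
    X = pd.DataFrame(X)
    all_vars = list(X.columns)
    if not all_vars:
        return StepwiseResult(_fit_subset(X, y, [], on_separation),
                              trace=[], p_enter=p_enter, p_remove=p_remove,
                              intercept_only=True)
    current = list(all_vars)
    trace: list[dict] = []
    visited = {tuple(sorted(current))}
    step = 0
    fit = _fit_subset(X, y, current, on_separation)
    while True:
        changed = False
        # removal: largest LRT p above p_remove
        if current:
            worst_p, worst_var, worst_lr = -1.0, None, 0.0
            for var in current:
                reduced = _fit_subset(
                    X, y, [v for v in current if v != var], on_separation)
                lr, _, p = likelihood_ratio_test(fit, reduced)
                if p > worst_p:
                    worst_p, worst_var, worst_lr = p, var, lr
            if worst_p > p_remove:
                current = [v for v in current if v != worst_var]
                fit = _fit_subset(X, y, current, on_separation)
                step += 1
                trace.append(dict(step=step, action="remove",
                                  variable=worst_var, lrt=worst_lr,
                                  p=worst_p))
                changed = True
        # re-entry: smallest LRT p below p_enter
        excluded = [v for v in all_vars if v not in current]
        if excluded:
            best_p, best_var, best_lr = 2.0, None, 0.0
            for var in excluded:
                bigger = _fit_subset(X, y, current + [var], on_separation)
                lr, _, p = likelihood_ratio_test(bigger, fit)
                if p < best_p:
                    best_p, best_var, best_lr = p, var, lr
            if best_p < p_enter:
                candidate = current + [best_var]
                if tuple(sorted(candidate)) not in visited:
                    current = candidate
                    fit = _fit_subset(X, y, current, on_separation)
                    step += 1
                    trace.append(dict(step=step, action="add",
                                      variable=best_var, lrt=best_lr,
                                      p=best_p))
                    changed = True
        if not changed:
            break
        visited.add(tuple(sorted(current)))
    return StepwiseResult(fit, trace=trace, p_enter=p_enter,
                          p_remove=p_remove,
                          intercept_only=not current)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, 1/(1-R^2) per predictor.

    R^2_j comes from the least-squares regression of predictor j on the
    others (plus an intercept); exact collinearity reports inf.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    n = len(X)
    for col in X.columns:
        yj = X[col].to_numpy()
        others = np.column_stack(
            [np.ones(n), X.drop(columns=col).to_numpy()])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
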