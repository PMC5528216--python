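"""Statistical battery for cohort discrimination by adiposity metrics.

Screens (normality, variance homogeneity, IQR outliers, collinearity),
two-sample comparisons, Pearson correlations, and binary logistic
regression with backward likelihood-ratio (LR) variable selection plus
Nagelkerke R-squared and Hosmer–Lemeshow calibration.

The response throughout is the migration cohort coded early = 0, late = 1.
Missing data are handled by listwise deletion per model, never imputation —
the per-model sample sizes are part of the scientific record.

Standard tests are delegated to scipy.stats and the logistic maximum
likelihood to statsmodels (Newton/IRLS); the selection procedure, the
pseudo-R-squared and the calibration chi-square are implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ComputationError, ConvergenceError, SeparationError, ValidationError

log = logging.getLogger(__name__)

#: Two-sided 95% normal quantile used for Wald confidence intervals.
Z_95 = 1.959964

#: Cohort coding used in every model.
COHORT_CODE = {"early": 0, "late": 1}

METRIC_COLUMNS = ("adipocyte_area_um2", "ai", "lipid_percent")

#: Predictor sets of the standard model battery.
MODEL_PREDICTORS: dict[str, tuple[str, ...]] = {
    "A": ("adipocyte_area_um2", "ai", "lipid_percent"),
    "B": ("ai", "lipid_percent"),
    "C": ("lipid_percent", "adipocyte_area_um2"),
    "D": ("adipocyte_area_um2", "ai"),
    "E": ("adipocyte_area_um2",),
    "F": ("ai",),
    "G": ("lipid_percent",),
}


@dataclass(frozen=True)
class SampleRecord:
    """One biopsy's cohort label and adiposity metrics (NaN = missing)."""

    sample_id: str
    cohort: str  # "early" or "late"
    adipocyte_area_um2: float = float("nan")
    ai: float = float("nan")
    lipid_percent: float = float("nan")


# ---------------------------------------------------------------------------
# Screens and simple tests
# ---------------------------------------------------------------------------


def test_normality(values) -> tuple[float, float]:
    """Shapiro–Wilk test; requires n >= 3 and nonzero variance."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValidationError("Shapiro–Wilk requires at least 3 values")
    if np.ptp(v) == 0:
        raise ValidationError("Shapiro–Wilk undefined for a constant vector")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def levene_test(*groups, center: str = "mean") -> tuple[float, float]:
    """Levene's variance-homogeneity test (classical mean-centred form).

    ``center="median"`` gives the Brown–Forsythe variant.
    """
    cleaned = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[~np.isnan(g)]
        if g.size < 2:
            raise ValidationError("each group needs n >= 2")
        cleaned.append(g)
    if len(cleaned) < 2:
        raise ValidationError("Levene test needs at least 2 groups")
    if all(np.ptp(g) == 0 for g in cleaned):
        # identical spread (zero) in every group: no evidence of heterogeneity
        return 0.0, 1.0
    stat, p = sps.levene(*cleaned, center=center)
    return float(stat), float(p)


def iqr_outliers(values, k: float = 2.2) -> np.ndarray:
    """Flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation.  With fewer than 4 values the rule
    is not meaningful; nothing is flagged and a warning is emitted.
    """
    v = np.asarray(values, dtype=float)
    flags = np.zeros(v.shape, dtype=bool)
    finite = ~np.isnan(v)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 values; IQR outlier screen not applied")
        return flags
    q1, q3 = np.percentile(v[finite], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags[finite] = (v[finite] < lo) | (v[finite] > hi)
    return flags


def vif(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    R^2_j is from an OLS regression (with intercept) of predictor j on the
    remaining predictors.  Perfect collinearity yields inf.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValidationError("VIF needs at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("VIF needs n > number of predictors")
    out = np.empty(X.shape[1])
    for j, col in enumerate(X.columns):
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def independent_t_test(
    a, b, *, log10_first: bool = False, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sided independent-samples t test; pooled-variance Student by default.

    ``log10_first`` log10-transforms both groups before testing (used for
    right-skewed metrics like the AI); ``welch`` switches to the
    unequal-variance form.
    Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if log10_first:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValidationError("log10 transform requires positive values")
        a, b = np.log10(a), np.log10(b)
    if not welch:
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if pooled == 0:
            raise ComputationError("zero pooled variance; t undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform (n - 2 df).

    Pairs with a missing value in either variable are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("zero variance; correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """One fitted binary logistic model (intercept listed first)."""

    predictors: list[str]  # without the intercept
    coef: np.ndarray  # [intercept, b1, ...]
    se: np.ndarray
    wald_p: np.ndarray
    llf: float
    n: int
    converged: bool

    @property
    def odds_ratio(self) -> np.ndarray:
        """exp(B) for the non-intercept coefficients."""
        return np.exp(self.coef[1:])

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef[1:] - Z_95 * self.se[1:])

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef[1:] + Z_95 * self.se[1:])

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf


@dataclass
class SelectionStep:
    retained: list[str]
    removal_p: dict[str, float]
    removed: str | None


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)


@dataclass
class FitDiagnostics:
    nagelkerke_r2: float
    hl_chi2: float
    hl_df: int
    hl_p: float


def fit_logistic(
    X: pd.DataFrame | np.ndarray | None,
    y,
    *,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood binary logistic fit (Newton/IRLS).

    Standard errors come from the inverse observed information; Wald
    p-values and 95% odds-ratio intervals follow.  Non-convergence and
    complete separation raise distinct errors.  ``X=None`` fits the
    intercept-only (null) model.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("response must be coded 0/1")
    if len(set(y)) < 2:
        raise ValidationError("both response classes must be present")
    if X is None:
        X = pd.DataFrame(index=range(len(y)))
    X = pd.DataFrame(X)
    names = [str(c) for c in X.columns]
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.isnan(design).any():
        raise ValidationError("predictors contain missing values; listwise-delete first")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = sm.Logit(y, design).fit(
                disp=0, maxiter=maxiter, tol=tol, warn_convergence=False
            )
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ) as exc:
            raise SeparationError(str(exc)) from exc
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        if np.linalg.norm(res.params) > 1e3:
            raise SeparationError(
                "diverging coefficients suggest (quasi-)separation"
            )
        raise ConvergenceError("logistic fit did not converge")
    return LogisticFit(
        predictors=names,
        coef=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        wald_p=np.asarray(res.pvalues, dtype=float),
        llf=float(res.llf),
        n=int(len(y)),
        converged=converged,
    )


def nagelkerke_r2(fit: LogisticFit, null_fit: LogisticFit, n: int) -> float:
    """Nagelkerke's rescaled Cox–Snell pseudo-R-squared, in [0, 1].

    Cox–Snell R^2 = 1 - exp(2 (LL0 - LL1) / n), divided by its maximum
    1 - exp(2 LL0 / n).  A fitted log-likelihood materially below the null
    signals a fitting bug and raises.
    """
    ll1, ll0 = fit.llf, null_fit.llf
    if ll1 < ll0 - 1e-8 * max(1.0, abs(ll0)):
        raise ComputationError("fitted model worse than null; fit is suspect")
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def hosmer_lemeshow(
    y, p_hat, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer–Lemeshow calibration chi-square over ranked-probability bins.

    Cases are ranked by fitted probability and split into ``groups``
    near-equal bins with ties kept together; the statistic sums
    (O - E)^2 / (E (1 - E/n_g)) over bins and is referred to chi-square
    with groups - 2 df.  Bins with zero expected variance are merged into
    a neighbour with a warning.
    Returns (chi2, df, p).
    """
    y = np.asarray(y, dtype=float)
    p_hat = np.asarray(p_hat, dtype=float)
    order = np.argsort(p_hat, kind="stable")
    ys, ps = y[order], p_hat[order]
    n = len(ys)
    edges = np.floor(np.arange(n) * groups / n).astype(int)
    # keep ties together: a run of equal p must share a bin
    for i in range(1, n):
        if ps[i] == ps[i - 1]:
            edges[i] = edges[i - 1]
    chi2 = 0.0
    used = 0
    pend_o = pend_e = pend_n = 0.0
    for g in np.unique(edges):
        sel = edges == g
        n_g = pend_n + sel.sum()
        obs = pend_o + ys[sel].sum()
        exp = pend_e + ps[sel].sum()
        var = exp * (1.0 - exp / n_g) if n_g else 0.0
        if var <= 0:
            warnings.warn("Hosmer–Lemeshow bin with zero expected variance; merging")
            pend_o, pend_e, pend_n = obs, exp, n_g
            continue
        chi2 += (obs - exp) ** 2 / var
        pend_o = pend_e = pend_n = 0.0
        used += 1
    if pend_n:
        used += 1  # trailing degenerate bin merged into the count
    df = max(used - 2, 1)
    return float(chi2), int(df), float(sps.chi2.sf(chi2, df))


def backward_lr_selection(
    X: pd.DataFrame,
    y,
    p_out: float = 0.10,
    *,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> tuple[LogisticFit, SelectionTrace]:
    """Backward stepwise removal by the likelihood-ratio criterion.

    Starting from the full model, each step refits without each current
    predictor in turn, computes the 1-df LR (deviance-difference) p-value
    for its removal, and drops the predictor with the largest p if that p
    is at least ``p_out``.  Stops when every remaining predictor's removal
    p falls below ``p_out``; an intercept-only final model is allowed.
    The same (listwise-deleted) cases are used at every step.
    """
    X = pd.DataFrame(X)
    current = list(X.columns)
    trace = SelectionTrace()
    fit = fit_logistic(X[current] if current else None, y, maxiter=maxiter, tol=tol)
    while current:
        pvals = {}
        for name in current:
            reduced = [c for c in current if c != name]
            red_fit = fit_logistic(
                X[reduced] if reduced else None, y, maxiter=maxiter, tol=tol
            )
            lr = 2.0 * (fit.llf - red_fit.llf)
            pvals[name] = float(sps.chi2.sf(max(lr, 0.0), 1))
        worst = max(pvals, key=pvals.get)
        if pvals[worst] >= p_out:
            current = [c for c in current if c != worst]
            trace.steps.append(
                SelectionStep(retained=list(current), removal_p=pvals, removed=worst)
            )
            fit = fit_logistic(
                X[current] if current else None, y, maxiter=maxiter, tol=tol
            )
        else:
            trace.steps.append(
                SelectionStep(retained=list(current), removal_p=pvals, removed=None)
            )
            break
    if not trace.steps:
        trace.steps.append(SelectionStep(retained=[], removal_p={}, removed=None))
    return fit, trace


# ---------------------------------------------------------------------------
# The model battery
# ---------------------------------------------------------------------------


@dataclass
class ModelResult:
    model: str
    predictors: tuple[str, ...]
    n: int
    fit: LogisticFit | None
    trace: SelectionTrace | None
    diagnostics: FitDiagnostics | None
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


def _encode_response(df: pd.DataFrame) -> np.ndarray:
    bad = set(df["cohort"].unique()) - set(COHORT_CODE)
    if bad:
        raise ValidationError(f"unknown cohort labels: {sorted(bad)}")
    return df["cohort"].map(COHORT_CODE).to_numpy(dtype=float)


def run_paper_models(
    records: pd.DataFrame,
    *,
    p_out: float = 0.10,
    hl_groups: int = 10,
    min_per_class: int = 10,
    univariate_on_complete_cases: bool = True,
) -> dict[str, ModelResult]:
    """Fit the seven-model battery A–G on one metrics table.

    Multi-predictor models (A–D) use backward-LR selection on their
    listwise-deleted subsets; the univariate models (E–G) are fitted by
    direct entry.  By default the univariate models are fitted on the
    complete-case subset (records carrying all three metrics) so that
    their sample size matches the head-to-head comparison in A; set
    ``univariate_on_complete_cases=False`` for per-model listwise deletion.
    Models with fewer than ``min_per_class`` cases in either class are
    skipped with a logged warning.
    """
    results: dict[str, ModelResult] = {}
    complete_all = records.dropna(subset=list(METRIC_COLUMNS))
    for name, predictors in MODEL_PREDICTORS.items():
        univariate = len(predictors) == 1
        if univariate and univariate_on_complete_cases:
            sub = complete_all
        else:
            sub = records.dropna(subset=list(predictors))
        n = len(sub)
        counts = sub["cohort"].value_counts()
        n_early = int(counts.get("early", 0))
        n_late = int(counts.get("late", 0))
        if min(n_early, n_late) < min_per_class:
            log.warning(
                "model %s skipped: %d early / %d late cases", name, n_early, n_late
            )
            results[name] = ModelResult(
                model=name,
                predictors=predictors,
                n=n,
                fit=None,
                trace=None,
                diagnostics=None,
                skipped_reason=f"fewer than {min_per_class} cases per class",
            )
            continue
        y = _encode_response(sub)
        X = sub[list(predictors)].astype(float)
        if univariate:
            fit = fit_logistic(X, y)
            trace = SelectionTrace(
                steps=[SelectionStep(retained=list(predictors), removal_p={}, removed=None)]
            )
        else:
            fit, trace = backward_lr_selection(X, y, p_out=p_out)
        null_fit = fit_logistic(None, y)
        nag = nagelkerke_r2(fit, null_fit, n)
        if fit.predictors:
            p_hat = _predict(fit, X[fit.predictors].to_numpy(dtype=float))
            chi2, df, p = hosmer_lemeshow(y, p_hat, groups=hl_groups)
        else:
            chi2, df, p = 0.0, hl_groups - 2, 1.0
        results[name] = ModelResult(
            model=name,
            predictors=predictors,
            n=n,
            fit=fit,
            trace=trace,
            diagnostics=FitDiagnostics(nag, chi2, df, p),
        )
        log.info("model %s: n=%d, retained=%s", name, n, fit.predictors)
    return results


def _predict(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    eta = fit.coef[0] + X @ fit.coef[1:]
    return 1.0 / (1.0 + np.exp(-eta))
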