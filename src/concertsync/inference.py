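"""Significance tests and trait/experience regressions.

Audience synchrony is declared significant when the mean dyadic effect
size differs from zero (one-sample t, two-sided — anti-phase synchrony
is meaningful) or, for the multivariate statistic, when the empirical
λmax exceeds its surrogate distribution (one-sample t on the
differences, one-sided greater, matching the directional hypothesis).

Synchrony contributions are linked to self-report covariates by
ordinary least squares with stepwise backward elimination: starting
from the full model, the predictor whose removal most decreases AIC is
dropped until no removal helps; remaining nonsignificant predictors are
then pruned at the chosen alpha and the model refitted.  The AIC used
is the Gaussian profile form n·ln(RSS/n) + 2k (k counting the
intercept); additive constants cancel in comparisons.

Caveat: dyadic ES values share members and are not independent; treating
them as independent observations replicates the source procedure and is
flagged as such, with a per-participant (contribution) test unit offered
as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .mv_susy import MvSynchrony

__all__ = [
    "TTestResult",
    "RegressionModel",
    "t_test_vs_zero",
    "mv_significance",
    "stepwise_backward_aic",
    "significance_stars",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    n: int
    mean: float
    sd: float
    one_sided: bool = False


@dataclass
class RegressionModel:
    response: str
    predictors: dict[str, tuple[float, float, float]]  # name -> (estimate, t, p)
    intercept: tuple[float, float, float]
    n: int
    r_square: float
    aic: float
    f_stat: float
    f_p: float
    dropped: list[str] = field(default_factory=list)
    # the AIC-minimum model before the alpha-pruning pass
    aic_predictors: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def t_test_vs_zero(values: Sequence[float]) -> TTestResult:
    """One-sample Student t of the mean against zero, two-sided."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two finite values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample")
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, n=n, mean=mean, sd=sd)


def mv_significance(res: MvSynchrony) -> TTestResult:
    """One-sided t: does empirical λmax exceed the surrogate λmax values?

    Tests the differences (λmax − λmax_surr_k) against zero, greater.
    """
    surr = np.asarray(res.lambda_surr, dtype=float)
    if len(surr) < 2:
        raise ValueError("need at least two surrogate values")
    diffs = res.lambda_max - surr
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate surrogate distribution")
    n = len(diffs)
    mean = float(diffs.mean())
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = float(stats.t.sf(t, df))
    return TTestResult(t=t, df=df, p=p, n=n, mean=mean, sd=sd, one_sided=True)


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    model = sm.OLS(y, design).fit()
    n = len(y)
    rss = float(model.ssr)
    k = design.shape[1]  # parameters incl. intercept
    aic = n * math.log(rss / n) + 2 * k if rss > 0 else -math.inf
    return model, aic


def stepwise_backward_aic(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    alpha: float = 0.05,
) -> RegressionModel:
    """Backward elimination to the AIC minimum, then alpha pruning.

    Rows with any missing value among response/predictors are dropped
    listwise.  AIC ties are broken by dropping the predictor with the
    largest p-value.  The final model retains only predictors with
    p < alpha (or is the intercept-only null model).
    """
    predictors = list(predictors)
    cols = [response] + predictors
    data = table[cols].dropna()
    n = len(data)
    if n <= len(predictors) + 2:
        raise ValueError("too few complete rows for the requested predictors")
    y = data[response].to_numpy(dtype=float)
    X_full = data[predictors].astype(float)
    rank = np.linalg.matrix_rank(sm.add_constant(X_full, has_constant="add").to_numpy())
    if rank < len(predictors) + 1:
        bad = _collinear_columns(X_full)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    current = list(predictors)
    dropped: list[str] = []
    model, aic = _fit_ols(y, X_full[current])
    while current:
        candidates = []
        for p_name in current:
            reduced = [c for c in current if c != p_name]
            _, aic_red = _fit_ols(y, X_full[reduced])
            candidates.append((aic_red, p_name))
        best_aic = min(a for a, _ in candidates)
        if best_aic >= aic - 1e-12:
            break
        tied = [p_name for a, p_name in candidates if a <= best_aic + 1e-12]
        if len(tied) > 1:
            pvals = model.pvalues
            tied.sort(key=lambda p_name: -pvals[p_name])
        drop = tied[0]
        current.remove(drop)
        dropped.append(drop)
        model, aic = _fit_ols(y, X_full[current])

    aic_predictors = {
        name: (float(model.params[name]), float(model.tvalues[name]), float(model.pvalues[name]))
        for name in current
    }

    # alpha pruning of nonsignificant survivors
    while current:
        pvals = model.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        current.remove(worst)
        dropped.append(worst)
        model, aic = _fit_ols(y, X_full[current])

    params, tvals, pvals = model.params, model.tvalues, model.pvalues
    retained = {
        name: (float(params[name]), float(tvals[name]), float(pvals[name]))
        for name in current
    }
    f_stat = float(model.fvalue) if current else float("nan")
    f_p = float(model.f_pvalue) if current else float("nan")
    return RegressionModel(
        response=response,
        predictors=retained,
        intercept=(float(params["const"]), float(tvals["const"]), float(pvals["const"])),
        n=n,
        r_square=float(model.rsquared) if current else 0.0,
        aic=aic,
        f_stat=f_stat,
        f_p=f_p,
        dropped=dropped,
        aic_predictors=aic_predictors,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns that do not increase the design rank when added."""
    bad, kept = [], []
    base = np.ones((len(X), 1))
    for c in X.columns:
        trial = np.column_stack([base] + [X[k].to_numpy() for k in kept + [c]])
        if np.linalg.matrix_rank(trial) <= len(kept) + 1:
            bad.append(c)
        else:
            kept.append(c)
    return bad


def significance_stars(p: float) -> str:
    """Rendering thresholds 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""
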