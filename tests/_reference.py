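"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written as plainly as possible (explicit loops,
scipy.stats.pearsonr, power iteration) and never calls the package's
own numerics for the quantity it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import pearsonr


def susy_es_bruteforce(
    a: np.ndarray,
    b: np.ndarray,
    rate: float,
    segment_s: float,
    max_lag_s: float,
    clip_eps: float = 1e-6,
):
    """SUSY effect size by explicit loops over segments, lags and all
    n(n-1) surrogate pairings.  Assumes complete, non-degenerate data."""
    seg_len = int(round(segment_s * rate))
    max_lag = int(round(max_lag_s * rate))
    n = min(len(a), len(b)) // seg_len
    segs_a = [a[i * seg_len : (i + 1) * seg_len] for i in range(n)]
    segs_b = [b[i * seg_len : (i + 1) * seg_len] for i in range(n)]

    def mean_z(x, y):
        zs = []
        for tau in range(-max_lag, max_lag + 1):
            if tau >= 0:
                xx, yy = x[: seg_len - tau], y[tau:]
            else:
                xx, yy = x[-tau:], y[: seg_len + tau]
            r = pearsonr(xx, yy).statistic
            r = max(min(r, 1 - clip_eps), -(1 - clip_eps))
            zs.append(math.atanh(r))
        return sum(zs) / len(zs)

    z_real = sum(mean_z(segs_a[i], segs_b[i]) for i in range(n)) / n
    surr = [
        mean_z(segs_a[i], segs_b[j]) for i in range(n) for j in range(n) if i != j
    ]
    surr_mean = sum(surr) / len(surr)
    surr_sd = math.sqrt(sum((s - surr_mean) ** 2 for s in surr) / (len(surr) - 1))
    es = (z_real - surr_mean) / surr_sd
    return z_real, surr_mean, surr_sd, es


def lambda_max_power_iteration(x: np.ndarray, tol: float = 1e-14, iters: int = 10_000) -> float:
    """Largest eigenvalue of the row-correlation matrix by power iteration."""
    c = np.corrcoef(x)
    m = c.shape[0]
    v = np.ones(m) / math.sqrt(m)
    lam = 0.0
    for _ in range(iters):
        w = c @ v
        lam_new = float(np.linalg.norm(w))
        v = w / lam_new
        if abs(lam_new - lam) < tol:
            break
        lam = lam_new
    return lam


def frame_diff_loop(a: np.ndarray, b: np.ndarray, x0: int, y0: int, x1: int, y1: int,
                    threshold: float) -> int:
    """Per-pixel loop count of changed pixels inside a rectangle."""
    count = 0
    for y in range(y0, y1):
        for x in range(x0, x1):
            if abs(float(a[y, x]) - float(b[y, x])) > threshold:
                count += 1
    return count


def all_subsets_aic_model(table, response: str, predictors: list[str], alpha: float = 0.05):
    """Exhaustive AIC-minimum subset, followed by the same alpha pruning
    rule as the stepwise procedure.  Returns the retained predictor set."""
    import itertools

    import statsmodels.api as sm

    data = table[[response] + predictors].dropna()
    y = data[response].to_numpy(dtype=float)
    n = len(y)

    def fit(cols):
        X = sm.add_constant(data[list(cols)].astype(float), has_constant="add")
        model = sm.OLS(y, X).fit()
        rss = float(model.ssr)
        k = X.shape[1]
        aic = n * math.log(rss / n) + 2 * k if rss > 0 else -math.inf
        return model, aic

    best, best_aic = (), math.inf
    for r in range(len(predictors) + 1):
        for combo in itertools.combinations(predictors, r):
            _, aic = fit(combo)
            if aic < best_aic - 1e-12:
                best, best_aic = combo, aic
    current = list(best)
    model, _ = fit(current)
    while current:
        pv = model.pvalues.drop("const")
        worst = pv.idxmax()
        if pv[worst] < alpha:
            break
        current.remove(worst)
        model, _ = fit(current)
    return set(current), set(best)
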