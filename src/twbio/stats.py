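"""Statistical screening battery: Spearman rank correlations with exact
small-n permutation p-values, PCA on standardized characterization
tables, and an AICc-based comparison of time-trend regression models.

The study design is tiny (seven wastewater samples), which drives the
numerical choices here: exact permutation null distributions for
Spearman tests at n <= 9, the small-sample corrected Akaike criterion
(AICc) for model comparison, and no multiple-testing correction (each
metric/characteristic pair is screened separately; a Benjamini-Hochberg
helper is available but off by default).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "PCAResult",
    "spearman",
    "pca",
    "aicc",
    "fit_time_models",
    "metric_screen",
    "benjamini_hochberg",
]

#: largest n for which the exact permutation null is enumerated (n! tests)
EXACT_PERMUTATION_MAX_N = 9


@dataclass
class CorrelationResult:
    metric: str
    covariate: str
    rho: float
    p_value: float
    n: int
    method: str  # 'exact-permutation' or 't-approximation'


@dataclass
class PCAResult:
    """Loadings (variables x components), scores (samples x components)
    and percent variance explained per component."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all n! assignments of the y-ranks.  rho for permuted
    ranks is monotone in sum(rx * ry_perm), so only dot products are
    recomputed per permutation.
    """
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c @ rx_c) * np.sum(ry_c**2, axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, metric: str = "x", covariate: str = "y") -> CorrelationResult:
    """Spearman rank correlation with a small-n exact permutation test.

    Ties get mid-ranks; rho is the Pearson correlation of the ranks.
    Pairs with a missing value in either input are dropped.  For
    n <= 9 the two-sided p-value comes from full enumeration of the
    n! rank permutations; beyond that, the usual t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(metric, covariate, math.nan, math.nan, n,
                                 "undefined: zero variance")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "t-approximation"
    return CorrelationResult(metric, covariate, rho, p, n, method)


def pca(table: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """Principal component analysis of a samples-by-variables table.

    Standardization (z-score, sample SD) is the default because the
    characterization variables span orders of magnitude across units —
    equivalent to an eigendecomposition of the correlation matrix.
    Constant columns are dropped with a warning under standardization.
    Sign convention: within each component the largest-magnitude loading
    is made positive, so results are deterministic.
    """
    X = table.astype(float)
    if X.isna().any().any():
        X = X.dropna(axis=0)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    sd = X.std(ddof=1)
    if standardize:
        constant = sd[sd == 0].index.tolist()
        if constant:
            warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
            X = X.drop(columns=constant)
            sd = sd.drop(constant)
        Z = (X - X.mean()) / sd
    else:
        Z = X - X.mean()
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for j in range(Vt.shape[0]):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigvals = s**2
    var_pct = 100.0 * eigvals / eigvals.sum()
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp_names)
    scores = pd.DataFrame(U * s, index=X.index, columns=comp_names)
    return PCAResult(loadings=loadings, scores=scores, variance_explained=var_pct)


def aicc(sse: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for a Gaussian OLS fit.

    AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n-k-1), with k counting the
    regression coefficients plus the error variance.  Additive Gaussian
    constants are omitted — they cancel in every AICc difference.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, k={k} leaves no residual df")
    if sse <= 0:
        raise ValueError("SSE must be positive for the log-likelihood term")
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _scaled_time(t: np.ndarray) -> np.ndarray:
    # centering and scaling before squaring keeps the design well conditioned;
    # OLS fit and AICc are invariant to this basis change
    return (t - t.mean()) / t.std(ddof=1)


def fit_time_models(data: pd.DataFrame, covariate: str | None = "x") -> pd.DataFrame:
    """Compare the three time-trend regression models by AICc.

    ``data`` is a long table with columns ``y`` (response), ``time``,
    ``sample`` (categorical wastewater identity), ``y_tw`` (per-sample
    initial value of the response, the intercept covariate) and — for
    the third model — a continuous sample characteristic named by
    ``covariate``.  The candidate models are

    1. Time:          y ~ a*y_tw + poly(time, 2)
    2. Wastewater ID: y ~ a*y_tw + poly(time, 2) + poly(time, 2):sample
    3. TW x:          y ~ a*y_tw + poly(time, 2) + poly(time, 2):x

    Models that would leave no residual degrees of freedom are excluded
    with an ``overfit`` flag.  A covariate model is deemed *relevant*
    when its AICc is below the Time-only model's AICc and within 4 units
    of the best model.
    """
    import statsmodels.formula.api as smf

    df = data.copy()
    required = {"y", "time", "sample", "y_tw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df["time"].nunique() < 3:
        raise ValueError("need at least 3 distinct time points")
    df["tc"] = _scaled_time(df["time"].to_numpy(dtype=float))
    df["tc2"] = df["tc"] ** 2

    formulas = {
        "Time": "y ~ y_tw + tc + tc2",
        "Wastewater ID": "y ~ y_tw + tc + tc2 + tc:C(sample) + tc2:C(sample)",
    }
    if covariate is not None:
        if covariate not in df.columns:
            raise ValueError(f"covariate column {covariate!r} not in data")
        df["_x"] = df[covariate].astype(float)
        formulas[f"TW {covariate}"] = "y ~ y_tw + tc + tc2 + tc:_x + tc2:_x"

    n = len(df)
    rows = {}
    for name, formula in formulas.items():
        fit = smf.ols(formula, data=df).fit()
        k = int(fit.df_model) + 1 + 1  # coefficients (+intercept) + sigma
        if n - k - 1 <= 0:
            rows[name] = {"k": k, "sse": math.nan, "aicc": math.nan,
                          "overfit": True}
            continue
        sse = float(fit.ssr)
        rows[name] = {"k": k, "sse": sse, "aicc": aicc(sse, n, k),
                      "overfit": False}
    table = pd.DataFrame(rows).T
    valid = table.loc[~table["overfit"].astype(bool), "aicc"]
    best = valid.min()
    table["delta_aicc"] = table["aicc"] - best
    aicc_time = table.loc["Time", "aicc"]
    table["relevant"] = [
        (not row["overfit"])
        and name != "Time"
        and row["aicc"] < aicc_time
        and row["delta_aicc"] <= 4.0
        for name, row in table.iterrows()
    ]
    return table


def metric_screen(
    metrics: pd.DataFrame,
    characteristics: pd.DataFrame,
) -> pd.DataFrame:
    """All pairwise Spearman tests of bioassay metrics vs characteristics.

    Both tables are keyed (indexed) by sample id.  Each pair is tested
    separately with its own p-value, without multiplicity correction.
    Pairs with fewer than 3 complete observations are skipped with a
    note row (rho and p NaN).
    """
    common = metrics.index.intersection(characteristics.index)
    rows = []
    for m in metrics.columns:
        for c in characteristics.columns:
            x = metrics.loc[common, m].to_numpy(dtype=float)
            y = characteristics.loc[common, c].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            if keep.sum() < 3:
                rows.append({"metric": m, "covariate": c, "rho": math.nan,
                             "p_value": math.nan, "n": int(keep.sum()),
                             "method": "skipped: <3 complete pairs"})
                continue
            res = spearman(x[keep], y[keep], metric=m, covariate=c)
            rows.append(vars(res))
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values; optional — the default screen reports raw p."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
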