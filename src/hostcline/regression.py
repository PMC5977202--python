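"""Cross-experiment association regressions and stepwise-AIC model search.

Per-SNP frequency-response vectors from independent experiments are
regressed on one another (simple OLS) or combined in a forward/backward
stepwise multiple regression scored by Gaussian AIC,

    AIC = n * ln(RSS / n) + 2k,   k = fitted coefficients incl. intercept,

which matches the usual stepwise convention up to an additive constant
that cancels in comparisons.  Per-SNP observations are treated as
independent in the fit; LD-induced dependence between SNPs is
acknowledged but not modelled, so classical p-values are descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RegressionResult", "fit_simple_regression", "stepwise_aic"]


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    aic: float
    retained: list[str]
    n: int
    r: float | None = None  # signed, simple regression only

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coeff": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    return n * np.log(rss / n) + 2.0 * k


def _result_from_fit(fit, retained, n, r=None) -> RegressionResult:
    k = len(fit.params)
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        fvalue=float(fit.fvalue) if k > 1 else np.nan,
        f_pvalue=float(fit.f_pvalue) if k > 1 else np.nan,
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        aic=_gaussian_aic(float(fit.ssr), n, k),
        retained=list(retained),
        n=n,
        r=r,
    )


def fit_simple_regression(y, x, name: str = "x") -> RegressionResult:
    """OLS of y on x over pairwise-complete SNPs; reports signed r."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (x, y) pairs")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0:
        raise ValueError("predictor has zero variance")
    X = sm.add_constant(pd.DataFrame({name: xs}))
    fit = sm.OLS(ys, X).fit()
    r = float(np.sign(fit.params[name]) * np.sqrt(max(fit.rsquared, 0.0)))
    return _result_from_fit(fit, [name], int(ok.sum()), r=r)


def _fit_subset(y: np.ndarray, X: pd.DataFrame, cols: tuple):
    design = sm.add_constant(X[list(cols)]) if cols else pd.DataFrame(
        {"const": np.ones(len(y))}, index=X.index
    )
    fit = sm.OLS(y, design).fit()
    rank = np.linalg.matrix_rank(np.asarray(design))
    aic = _gaussian_aic(float(fit.ssr), len(y), rank)
    return fit, aic


def stepwise_aic(y, X: pd.DataFrame, tol: float = 1e-10) -> RegressionResult:
    """Stepwise model search in both directions, starting from the full model.

    At each step every single-predictor addition and deletion is scored by
    Gaussian AIC and the best move taken; AIC ties break toward the
    smaller model, and among equal-sized ties toward the earlier column
    order (so a duplicated predictor retains exactly one copy).
    Complete-case rows over y and all candidates.  Returns the selected
    model with classical coefficient and model-level statistics.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1).to_numpy()
    y, X = y[ok], X.loc[ok].reset_index(drop=True)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than candidate predictors")
    if all(X[c].std() == 0 for c in X.columns):
        raise ValueError("all candidate predictors are constant")
    order = {c: i for i, c in enumerate(X.columns)}

    cache: dict[tuple, float] = {}

    def score(cols: tuple) -> float:
        if cols not in cache:
            cache[cols] = _fit_subset(y, X, cols)[1]
        return cache[cols]

    current = tuple(X.columns)
    current_aic = score(current)
    while True:
        moves = []
        for c in current:  # deletions
            cand = tuple(k for k in current if k != c)
            moves.append((score(cand), len(cand), order[c], cand))
        for c in X.columns:  # additions
            if c in current:
                continue
            cand = tuple(sorted(current + (c,), key=order.get))
            moves.append((score(cand), len(cand), order[c], cand))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_aic, best_size, _, best_cols = moves[0]
        if best_aic < current_aic - tol or (
            abs(best_aic - current_aic) <= tol and best_size < len(current)
        ):
            current, current_aic = best_cols, best_aic
        else:
            break

    fit, aic = _fit_subset(y, X, current)
    res = _result_from_fit(fit, current, n)
    res.aic = aic
    return res
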