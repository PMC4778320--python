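"""Small statistical primitives shared across stages.

The ordinary-least-squares fit is implemented directly from the normal
equations because the switching model's coefficient signs and per-coefficient
t-test p-values are the core statistic of the pipeline; tests cross-check it
against statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class OlsFit:
    """Coefficients and two-sided t-test p-values of an OLS fit.

    Attributes are ordered like the design-matrix columns (intercept first
    when ``add_intercept`` was used).
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    rss: float


def ols(X: np.ndarray, y: np.ndarray, add_intercept: bool = True) -> OlsFit:
    """OLS via normal equations with per-coefficient two-sided t-tests.

    Parameters
    ----------
    X : (n, k) design matrix (without intercept if ``add_intercept``).
    y : (n,) response.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    k = X.shape[1]
    df = n - k
    if df <= 0:
        raise ValueError(f"not enough samples for OLS: n={n}, k={k}")
    XtX = X.T @ X
    Xty = X.T @ y
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ Xty
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / df
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return OlsFit(beta=beta, se=se, t=t, p=p, df_resid=df, rss=rss)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test; returns (t, two-sided p).

    Degenerate inputs (a group of <2 values, or two zero-variance groups with
    equal means) return (0.0, 1.0) rather than NaN so callers can treat them
    as uninformative.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (statsmodels implementation)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def quantile75(values: np.ndarray) -> float:
    """75th percentile with linear interpolation between order statistics.

    Matches the convention where the p-th quantile sits at h = (n-1)p + 1
    (numpy's default "linear" method, R type 7).
    """
    return float(np.quantile(np.asarray(values, dtype=float), 0.75))
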