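"""Time-domain Granger causality between the two regional signals.

Per trial: bandpass the raw signals, test stationarity with the Augmented
Dickey-Fuller test, difference until stationary (both channels to the same
order so the bivariate model stays balanced), select the lag order by
information criterion, then compute Granger causality in both directions as
the log ratio of restricted-to-full residual variances (nats), with
significance from the standard nested-model F test. Summaries average GC
exclusively over significant trials (p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .preprocess import bandpass

__all__ = [
    "GCResult",
    "adf_test",
    "difference_until_stationary",
    "select_lag_order",
    "granger_causality",
    "summarize_gc",
    "gc_pipeline",
]


@dataclass
class GCResult:
    """Directional Granger causality for one trial.

    ``gc_ab`` is the influence of the first series on the second (A->B) in
    nats; ``d_a``/``d_b`` are the differencing orders that were applied
    before fitting; ``n_effective`` is the number of regression rows used.
    """

    gc_ab: float
    gc_ba: float
    lag_order: int
    d_a: int = 0
    d_b: int = 0
    p_ab: float = np.nan
    p_ba: float = np.nan
    n_effective: int = 0

    def __post_init__(self) -> None:
        if self.gc_ab < -1e-10 or self.gc_ba < -1e-10:
            raise ValueError("GC values must be nonnegative (nested models)")
        if self.lag_order < 1:
            raise ValueError("lag_order must be >= 1")


def adf_test(series: np.ndarray, alpha: float = 0.05) -> tuple[bool, float, float]:
    """Augmented Dickey-Fuller unit-root test (constant term, no trend).

    Returns ``(is_stationary, statistic, p_value)``; stationary iff
    p < alpha. The ADF lag length is chosen by AIC up to the Schwert bound
    ``12 * (n/100)**0.25``. A constant series carries no unit-root
    information and is reported stationary with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 30:
        raise ValueError(f"series of {x.size} samples too short for ADF (need >= 30)")
    if np.ptp(x) == 0:
        warnings.warn("constant series: ADF non-informative, treated as stationary",
                      RuntimeWarning, stacklevel=2)
        return True, np.nan, np.nan
    stat, p, *_ = adfuller(x, regression="c", autolag="AIC")
    return bool(p < alpha), float(stat), float(p)


def difference_until_stationary(
    series: np.ndarray, alpha: float = 0.05, max_diff: int = 2
) -> tuple[np.ndarray, int, bool]:
    """First-difference a series until the ADF test rejects a unit root.

    Returns ``(series, d, is_stationary)`` where ``d <= max_diff`` is the
    number of differences applied. If the series is still non-stationary at
    ``max_diff`` the flag is False and the caller should exclude the trial
    from the GC summary.
    """
    x = np.asarray(series, dtype=float)
    d = 0
    stationary, _, _ = adf_test(x, alpha)
    while not stationary and d < max_diff:
        x = np.diff(x)
        d += 1
        stationary, _, _ = adf_test(x, alpha)
    return x, d, stationary


def _lag_matrix(x: np.ndarray, y: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Stacked lag regressors: columns [x_{t-1}..x_{t-p}, y_{t-1}..y_{t-p}]."""
    n = x.size
    rows = n - order
    X = np.empty((rows, 2 * order))
    for k in range(1, order + 1):
        X[:, k - 1] = x[order - k : n - k]
        X[:, order + k - 1] = y[order - k : n - k]
    return X, np.arange(order, n)


def select_lag_order(
    x: np.ndarray,
    y: np.ndarray,
    max_order: int = 10,
    criterion: str = "bic",
) -> int:
    """Lag order minimizing an information criterion for the bivariate VAR.

    Fits VAR(p) by least squares for p = 1..max_order on a common sample
    (rows from ``max_order`` on, so criteria are comparable) and returns
    the argmin of BIC (default) or AIC on the residual covariance. A small
    ridge guards the log-determinant against degenerate (e.g. perfectly
    collinear) residual covariances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    if n <= 10 * max_order:
        max_order = max(1, (n - 1) // 10)
        warnings.warn(f"series too short; capping max_order at {max_order}",
                      RuntimeWarning, stacklevel=2)
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    rows = n - max_order
    Z = np.column_stack([x, y])
    best_p, best_ic = 1, np.inf
    for p in range(1, max_order + 1):
        X = np.empty((rows, 2 * p + 1))
        X[:, 0] = 1.0
        for k in range(1, p + 1):
            X[:, k] = x[max_order - k : n - k]
            X[:, p + k] = y[max_order - k : n - k]
        Y = Z[max_order:]
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        E = Y - X @ beta
        sigma = (E.T @ E) / rows
        ridge = 1e-12 * max(np.trace(sigma), 1e-30)
        sign, logdet = np.linalg.slogdet(sigma + ridge * np.eye(2))
        k_params = 2 * (2 * p + 1)
        penalty = np.log(rows) if criterion == "bic" else 2.0
        ic = logdet + penalty * k_params / rows
        if ic < best_ic - 1e-12:
            best_ic, best_p = ic, p
    return best_p


def _nested_ols(target: np.ndarray, own: np.ndarray, other: np.ndarray, order: int):
    """Restricted (own lags) vs full (own + other lags) OLS for one direction.

    Returns (gc, F, p, n_rows). GC = ln(RSS_restricted / RSS_full).
    """
    n = target.size
    rows = n - order
    ones = np.ones((rows, 1))
    own_lags = np.column_stack([own[order - k : n - k] for k in range(1, order + 1)])
    oth_lags = np.column_stack([other[order - k : n - k] for k in range(1, order + 1)])
    y = target[order:]
    Xr = np.hstack([ones, own_lags])
    Xf = np.hstack([ones, own_lags, oth_lags])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise np.linalg.LinAlgError(
            "singular design: lagged regressors are collinear "
            "(own-lag and cross-lag columns are linearly dependent)"
        )
    br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    bf, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    rss_r = float(np.sum((y - Xr @ br) ** 2))
    rss_f = float(np.sum((y - Xf @ bf) ** 2))
    gc = float(np.log(rss_r / rss_f)) if rss_f > 0 else np.inf
    df2 = rows - (2 * order + 1)
    if df2 <= 0:
        raise ValueError("not enough samples for the F test at this order")
    F = ((rss_r - rss_f) / order) / (rss_f / df2) if rss_f > 0 else np.inf
    p = float(stats.f.sf(F, order, df2))
    return max(gc, 0.0), F, p, rows


def granger_causality(x: np.ndarray, y: np.ndarray, order: int) -> GCResult:
    """Bidirectional time-domain Granger causality at a fixed lag order.

    GC(x->y) = ln(sigma^2_restricted / sigma^2_full) where the restricted
    model regresses y on its own ``order`` lags and the full model adds
    x's lags; significance is the nested-model F test. Both series must be
    stationary (difference first if not).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if order < 1:
        raise ValueError("order must be >= 1")
    rows = x.size - order
    if rows - (2 * order + 1) <= 0:
        raise ValueError(f"series of {x.size} samples too short for order {order}")
    gc_ab, _, p_ab, n_rows = _nested_ols(y, y, x, order)   # x -> y (A -> B)
    gc_ba, _, p_ba, _ = _nested_ols(x, x, y, order)        # y -> x (B -> A)
    return GCResult(
        gc_ab=gc_ab, gc_ba=gc_ba, lag_order=order,
        p_ab=p_ab, p_ba=p_ba, n_effective=n_rows,
    )


def summarize_gc(trials: list[GCResult], alpha: float = 0.05) -> dict:
    """Per-direction mean GC over significant trials (p < alpha) + counts.

    With no significant trials in a direction, its mean is ``None``.
    """
    if not trials:
        raise ValueError("empty trial list")
    out: dict = {"n_trials": len(trials)}
    for direction, gc_key, p_key in (("ab", "gc_ab", "p_ab"), ("ba", "gc_ba", "p_ba")):
        sig = [getattr(t, gc_key) for t in trials if getattr(t, p_key) < alpha]
        out[f"mean_gc_{direction}"] = float(np.mean(sig)) if sig else None
        out[f"n_significant_{direction}"] = len(sig)
        out[f"fraction_significant_{direction}"] = len(sig) / len(trials)
    return out


def gc_pipeline(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    alpha: float = 0.05,
    max_order: int = 10,
    max_diff: int = 2,
    criterion: str = "bic",
    prefilter: bool = True,
) -> GCResult | None:
    """Full per-trial GC chain: bandpass -> ADF/difference -> order -> GC.

    Both channels are differenced to the larger of their individually
    required orders so the bivariate model is balanced. Returns ``None``
    when a channel remains non-stationary at ``max_diff`` (trial excluded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if prefilter:
        x = bandpass(x, fs)
        y = bandpass(y, fs)
    _, dx, ok_x = difference_until_stationary(x, alpha, max_diff)
    _, dy, ok_y = difference_until_stationary(y, alpha, max_diff)
    if not (ok_x and ok_y):
        return None
    d = max(dx, dy)
    xs = np.diff(x, n=d) if d else x
    ys = np.diff(y, n=d) if d else y
    order = select_lag_order(xs, ys, max_order=max_order, criterion=criterion)
    result = granger_causality(xs, ys, order)
    result.d_a, result.d_b = d, d
    return result
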