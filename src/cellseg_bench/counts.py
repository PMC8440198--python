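"""Validation of model-based object counts against fluorescence-based counts.

Two complementary checks:

* explained variance of the fluorescence counts by the model counts on images
  below a confluence-linked count threshold (default 1,600 objects, roughly
  95% confluence), using the direct residuals y_fluorescence - y_model (not a
  fitted line); a fitted-line R^2 is also reported for reference;
* an iterative linearity-breakpoint test: for increasing maximum
  fluorescence-count candidates, compare the residual variances of an ordinary
  least-squares fit and a k-nearest-neighbor regression (both regressing the
  fluorescence count on the model count) with Levene's test, and stop at the
  first candidate rejecting equal variances at ``alpha`` (default 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.neighbors import KNeighborsRegressor

from .datamodel import CountSeries

DEFAULT_MAX_COUNT = 1600
DEFAULT_ALPHA = 1e-5
DEFAULT_K = 5


@dataclass
class ExplainedVariance:
    r_squared: float
    ss_residual: float
    ss_total: float
    r_squared_fitted: float  # alternative: R^2 of an OLS line, for reference
    n: int
    max_count: float


@dataclass
class LinearityResult:
    breakpoint_count: int
    breakdown_detected: bool
    candidates: list[int] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA
    k: int = DEFAULT_K
    levene_center: str = "median"


def explained_variance(series: CountSeries, max_count: float = DEFAULT_MAX_COUNT) -> ExplainedVariance:
    """R^2 = 1 - SS_residual / SS_total on images below ``max_count`` objects.

    SS_residual sums squared differences between fluorescence and model counts
    directly; SS_total sums squared deviations of the fluorescence counts from
    their mean over the retained images.
    """
    keep = series.y_fluorescence < max_count
    y_f = series.y_fluorescence[keep].astype(float)
    y_m = series.y_model[keep].astype(float)
    if y_f.size < 2:
        raise ValueError(f"need >= 2 rows below max_count={max_count}, got {y_f.size}")
    ss_res = float(np.sum((y_f - y_m) ** 2))
    ss_tot = float(np.sum((y_f - y_f.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("all retained fluorescence counts are equal; R^2 undefined")
    if np.ptp(y_m) == 0:  # constant regressor: the fitted line is the mean
        resid_line = y_f - y_f.mean()
    else:
        resid_line = y_f - np.polyval(np.polyfit(y_m, y_f, 1), y_m)
    return ExplainedVariance(
        r_squared=1.0 - ss_res / ss_tot,
        ss_residual=ss_res,
        ss_total=ss_tot,
        r_squared_fitted=1.0 - float(np.sum(resid_line**2)) / ss_tot,
        n=int(y_f.size),
        max_count=max_count,
    )


def _fit_residuals(y_f: np.ndarray, y_m: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of OLS (with intercept) and KNN regression of y_f on y_m."""
    beta = np.polyfit(y_m, y_f, 1)
    resid_lin = y_f - np.polyval(beta, y_m)
    knn = KNeighborsRegressor(n_neighbors=k)
    x = y_m.reshape(-1, 1)
    knn.fit(x, y_f)
    resid_knn = y_f - knn.predict(x)
    return resid_lin, resid_knn


def linearity_breakpoint(
    series: CountSeries,
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    levene_center: str = "median",
) -> LinearityResult:
    """Largest maximum-count candidate at which linearity is not rejected.

    Candidates are the ascending unique observed fluorescence counts; those
    admitting fewer than max(k + 2, 10) rows are skipped.  At each candidate
    the OLS and KNN residual sets over all rows with fluorescence count <= the
    candidate are compared with Levene's test; iteration stops at the first
    p-value below ``alpha`` and the previous candidate is the breakpoint.
    """
    y_f = series.y_fluorescence.astype(float)
    y_m = series.y_model.astype(float)
    order = np.argsort(y_f, kind="stable")
    y_f, y_m = y_f[order], y_m[order]
    min_rows = max(k + 2, 10)
    candidates = [int(c) for c in np.unique(y_f) if np.sum(y_f <= c) >= min_rows]
    if not candidates:
        raise ValueError(f"no candidate admits >= {min_rows} rows")
    tested: list[int] = []
    p_values: list[float] = []
    last_ok: int | None = None
    for cand in candidates:
        sel = y_f <= cand
        resid_lin, resid_knn = _fit_residuals(y_f[sel], y_m[sel], k)
        p = float(stats.levene(resid_lin, resid_knn, center=levene_center).pvalue)
        tested.append(cand)
        p_values.append(p)
        if p < alpha:
            if last_ok is None:
                # rejected at the very first candidate: report it directly
                last_ok = cand
            return LinearityResult(
                breakpoint_count=last_ok,
                breakdown_detected=True,
                candidates=tested,
                p_values=p_values,
                alpha=alpha,
                k=k,
                levene_center=levene_center,
            )
        last_ok = cand
    return LinearityResult(
        breakpoint_count=int(y_f.max()),
        breakdown_detected=False,
        candidates=tested,
        p_values=p_values,
        alpha=alpha,
        k=k,
        levene_center=levene_center,
    )
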