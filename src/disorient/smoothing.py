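"""Long-term trend extraction: discrete beta-kernel smoothing + stepwise
polynomial fit.

Daily proportion series live on a bounded time axis, and symmetric kernels
(Gaussian, Epanechnikov) leak weight past the first and last day, biasing
the smooth exactly where a year-long trend analysis is most fragile.  The
discrete beta kernel avoids this: the weights attached to day x are a Beta
density with shape parameters ``x/(T h) + 1`` and ``(T - x)/(T h) + 1``
evaluated on the rescaled day grid j/T, j = 0..T, and renormalised.  The
kernel's support is exactly the observation interval, the mode sits at the
evaluation day (including at the edges), and as h -> 0 the smoother tends
to the identity.

The smoothed favourable proportion is then summarised by ordinary
polynomial least squares with a stepwise degree choice: the selected degree
is the smallest one whose successor improves R^2 by less than ``delta_r2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def beta_kernel_weights(x: float, h: float, T: int) -> np.ndarray:
    """Normalised discrete beta-kernel weights for evaluation index x.

    Parameters
    ----------
    x : evaluation day index in [0, T]
    h : bandwidth (> 0), on the unit-interval scale of the rescaled axis
    T : last day index (grid is 0..T)
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if T < 1:
        raise ValueError("need at least two grid points")
    if not 0 <= x <= T:
        raise ValueError("evaluation index outside the grid")
    grid = np.arange(T + 1) / T
    a = x / (T * h) + 1.0
    b = (T - x) / (T * h) + 1.0
    w = stats.beta.pdf(grid, a, b)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        # extremely small h: density underflows everywhere except at x
        w = np.zeros(T + 1)
        w[int(round(x))] = 1.0
        return w
    return w / total


def _weight_matrix(T: int, h: float) -> np.ndarray:
    """(T+1, T+1) matrix whose row x holds beta_kernel_weights(x, h, T)."""
    grid = np.arange(T + 1) / T
    x = np.arange(T + 1)[:, None]
    a = x / (T * h) + 1.0
    b = (T - x) / (T * h) + 1.0
    w = stats.beta.pdf(grid[None, :], a, b)
    totals = w.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(totals[:, 0]) | (totals[:, 0] <= 0)
    if bad.any():
        w[bad] = 0.0
        w[bad, np.arange(T + 1)[bad]] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    return w / totals


@dataclass
class SmoothedSeries:
    """Kernel-smoothed daily proportions."""

    values: pd.DataFrame
    bandwidth: float
    renormalized: bool
    kernel: str = "discrete_beta"


def smooth_series(props: pd.DataFrame, h: float,
                  renormalize: bool = False) -> SmoothedSeries:
    """Smooth each proportion column independently with the beta kernel.

    Rows that are entirely NaN (zero-volume days) are excluded from the
    weighted means — the weights are renormalised over observed days rather
    than imputing — but the smooth is still evaluated at every day.
    With equal bandwidths per category the smoothed simplex coordinates sum
    to 1 automatically; ``renormalize`` forces the sum exactly when observed
    rows are missing unevenly.
    """
    values = np.asarray(props, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    Tn = values.shape[0]
    if Tn < 2:
        raise ValueError("need at least two days")
    T = Tn - 1
    observed = ~np.isnan(values)
    if not observed.any():
        raise ValueError("all values are missing")
    W = _weight_matrix(T, h)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        mask = observed[:, j]
        if not mask.any():
            raise ValueError(f"column {j} has no observed values")
        Wj = W[:, mask]
        out[:, j] = Wj @ values[mask, j] / Wj.sum(axis=1)
    if renormalize:
        out = out / out.sum(axis=1, keepdims=True)
    cols = props.columns if isinstance(props, pd.DataFrame) else None
    idx = props.index if isinstance(props, pd.DataFrame) else None
    return SmoothedSeries(pd.DataFrame(out, columns=cols, index=idx),
                          bandwidth=h, renormalized=renormalize)


def loo_cv_error(props: pd.DataFrame, h: float) -> float:
    """Mean squared leave-one-out prediction error for bandwidth h.

    Each observed day is predicted from all other observed days (its own
    weight zeroed and the rest renormalised); the error averages over days
    and proportion columns.
    """
    values = np.asarray(props, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    T = values.shape[0] - 1
    W = _weight_matrix(T, h)
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    sq_sum = 0.0
    n_obs = 0
    for j in range(values.shape[1]):
        mask = ~np.isnan(values[:, j])
        Wj = W[np.ix_(mask, mask)]
        denom = Wj.sum(axis=1)
        ok = denom > 0
        pred = Wj[ok] @ values[mask, j] / denom[ok]
        resid = pred - values[mask, j][ok]
        sq_sum += float((resid ** 2).sum())
        n_obs += int(ok.sum())
    if n_obs == 0:
        raise ValueError("no leave-one-out predictions possible")
    return sq_sum / n_obs


def cv_bandwidth(props: pd.DataFrame, h_grid) -> tuple[float, pd.DataFrame]:
    """Pick the bandwidth minimising leave-one-out squared error.

    Ties (within 1e-15 relative) break toward the larger h, i.e. the
    smoother fit.  Returns (h_star, table of errors per grid value).
    """
    h_grid = np.asarray(list(h_grid), dtype=float)
    if h_grid.size == 0:
        raise ValueError("empty bandwidth grid")
    if (h_grid <= 0).any():
        raise ValueError("bandwidths must be positive")
    values = np.asarray(props, dtype=float)
    n_days = values.shape[0] if values.ndim > 1 else len(values)
    if n_days < 3:
        raise ValueError("need at least three days for cross-validation")
    errs = np.array([loo_cv_error(props, h) for h in h_grid])
    best = errs.min()
    candidates = h_grid[errs <= best * (1 + 1e-10) + 1e-20]
    h_star = float(candidates.max())
    return h_star, pd.DataFrame({"h": h_grid, "loo_error": errs})


@dataclass
class TrendFit:
    """Stepwise polynomial fit of a smoothed proportion series.

    ``coefficients`` are on the centered/scaled day index
    z = (t - t_mean) / t_std (ascending powers); ``coefficients_raw`` are
    the same polynomial re-expressed in the raw day index.
    """

    selected_degree: int
    r2_by_degree: dict[int, float]
    coefficients: np.ndarray
    coefficients_raw: np.ndarray
    coef_stderr: np.ndarray
    coef_ci: np.ndarray  # (k, 2) at ci_level, scaled basis
    ci_level: float
    scale_mean: float
    scale_std: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        z = (np.asarray(t, dtype=float) - self.scale_mean) / self.scale_std
        return np.polynomial.polynomial.polyval(z, self.coefficients)

    def vertex_day(self) -> float:
        """Stationary point of a degree-2 fit, on the raw day-index scale."""
        if self.selected_degree != 2 or self.coefficients[2] == 0:
            raise ValueError("vertex is defined for a quadratic fit only")
        z_v = -self.coefficients[1] / (2 * self.coefficients[2])
        return float(z_v * self.scale_std + self.scale_mean)

    def to_dict(self) -> dict:
        return {
            "selected_degree": self.selected_degree,
            "r2_by_degree": {int(k): float(v) for k, v in self.r2_by_degree.items()},
            "coefficients_scaled": self.coefficients.tolist(),
            "coefficients_raw": self.coefficients_raw.tolist(),
            "coef_stderr": self.coef_stderr.tolist(),
            "coef_ci": self.coef_ci.tolist(),
            "ci_level": self.ci_level,
            "scale_mean": self.scale_mean,
            "scale_std": self.scale_std,
        }


def fit_polynomial_trend(y, max_degree: int = 5, delta_r2: float = 0.01,
                         ci_level: float = 0.95) -> TrendFit:
    """OLS polynomial fits of degree 0..max_degree with stepwise selection.

    The day index is centered and scaled before building the Vandermonde
    design (conditioning).  The selected degree is the smallest d >= 1 such
    that R^2(d+1) - R^2(d) < delta_r2; if every step gains at least
    delta_r2, max_degree is selected.  A constant input selects degree 0
    with R^2 defined as 1.
    """
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    t = np.arange(len(y), dtype=float)[mask]
    yv = y[mask]
    if len(yv) < max_degree + 2:
        raise ValueError("need at least max_degree + 2 observed points")
    mu, sd = float(t.mean()), float(t.std())
    if sd == 0:
        sd = 1.0
    z = (t - mu) / sd

    sst = float(((yv - yv.mean()) ** 2).sum())
    r2: dict[int, float] = {}
    fits: dict[int, sm.regression.linear_model.RegressionResultsWrapper] = {}
    if np.ptp(yv) == 0:
        coefs = np.array([yv[0]])
        return TrendFit(0, {0: 1.0}, coefs, coefs.copy(),
                        np.array([0.0]), np.array([[yv[0], yv[0]]]),
                        ci_level, mu, sd)
    for d in range(max_degree + 1):
        X = np.vander(z, N=d + 1, increasing=True)
        res = sm.OLS(yv, X).fit()
        fits[d] = res
        r2[d] = 0.0 if d == 0 else float(res.rsquared)
    selected = max_degree
    for d in range(1, max_degree):
        if r2[d + 1] - r2[d] < delta_r2:
            selected = d
            break
    res = fits[selected]
    coefs = np.asarray(res.params, dtype=float)
    ci = np.asarray(res.conf_int(alpha=1 - ci_level), dtype=float)
    # re-express P(z) with z = (t - mu)/sd as a polynomial in t
    p_scaled = np.polynomial.Polynomial(coefs)
    p_raw = p_scaled(np.polynomial.Polynomial([-mu / sd, 1.0 / sd]))
    raw = np.zeros(selected + 1)
    raw[: len(p_raw.coef)] = p_raw.coef
    return TrendFit(selected, r2, coefs, raw,
                    np.asarray(res.bse, dtype=float), ci, ci_level, mu, sd)
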