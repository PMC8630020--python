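"""AOA relative-abundance regression and absolute-abundance estimation.

Across oxic sediment cores the fraction of ammonia-oxidizing archaea in
the total community declines with *relative* depth in the oxic zone,
x = z / OPD (0 at the sediment surface, 1 at the oxic-anoxic boundary).
The decline is fitted as y = a * exp(b * x) by nonlinear least squares on
the untransformed fractions (percent).  The fit, with its parameter
covariance, yields point predictions and 95% confidence bands that can be
multiplied by total cell numbers to estimate absolute AOA abundances,
which in turn can be cross-validated against amoA qPCR counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


def relative_depth(z, opd: float):
    """x = z / OPD; values above 1 lie below the oxic zone."""
    if not opd > 0:
        raise ValueError("OPD must be positive")
    return np.asarray(z, dtype=float) / opd


@dataclass
class RegressionFit:
    """Exponential-decay fit y = a exp(b x) with inference metadata."""

    a: float  # percent at x = 0
    b: float  # decay per unit relative depth (<= 0 for a decline)
    covariance: np.ndarray  # 2x2, order (a, b)
    r_squared: float
    n: int
    residual_variance: float

    def predict(self, x):
        return self.a * np.exp(self.b * np.asarray(x, dtype=float))


def fit_exponential_decay(x, y, *, log_space: bool = False) -> RegressionFit:
    """Fit y = a exp(b x) to fractions y (percent) at relative depths x.

    The default minimises untransformed residuals (matching the common
    curve-fitting-tool workflow); ``log_space=True`` fits ln y instead,
    which weighs relative errors equally.  Requires n >= 3, x in [0, 1]
    with some spread, and y >= 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("relative depths must lie in [0, 1]")
    if np.any(y < 0):
        raise ValueError("fractions must be >= 0")
    if np.ptp(x) == 0:
        raise ValueError("no depth contrast: all relative depths identical")

    dof = max(x.size - 2, 1)
    sstot = float(np.sum((y - y.mean()) ** 2))

    if np.ptp(y) == 0:  # constant data: a = c, b = 0 exactly
        return RegressionFit(
            a=float(y[0]), b=0.0, covariance=np.zeros((2, 2)),
            r_squared=0.0, n=int(x.size), residual_variance=0.0,
        )

    def _sandwich(a, b, resid):
        # heteroscedasticity-robust (HC1) parameter covariance: the
        # multiplicative scatter of the fractions makes residual variance
        # grow with the fitted value, which the classical (J'J)^-1 s^2
        # covariance understates near x = 0
        jac = np.column_stack([np.exp(b * x), a * x * np.exp(b * x)])
        jtj = jac.T @ jac
        try:
            bread = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            raise ValueError("singular Jacobian in exponential fit") from None
        meat = jac.T @ (jac * resid[:, None] ** 2)
        return bread @ meat @ bread * (x.size / dof)

    if log_space:
        pos = y > 0
        if pos.sum() < 3:
            raise ValueError("log-space fit needs >= 3 positive fractions")
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(slope))
        popt, pcov = optimize.curve_fit(
            lambda xx, la, b: la + b * xx, x[pos], np.log(y[pos]),
            p0=(np.log(p0[0]), p0[1]),
        )
        # delta-method back-transform of the (ln a, b) covariance
        a = float(np.exp(popt[0]))
        jac = np.diag([a, 1.0])
        cov = jac @ pcov @ jac.T
        b = float(popt[1])
        resid = y - a * np.exp(b * x)
    else:
        p0 = (max(float(y.max()), 1e-6), -1.0)
        try:
            popt, pcov = optimize.curve_fit(
                lambda xx, a, b: a * np.exp(b * xx), x, y, p0=p0,
                bounds=([1e-12, -10.0], [100.0, 10.0]), maxfev=10000,
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            raise ValueError(f"exponential fit failed to converge: {exc}") from exc
        a, b = float(popt[0]), float(popt[1])
        resid = y - a * np.exp(b * x)
        cov = _sandwich(a, b, resid)
    if not np.all(np.isfinite(cov)):
        raise ValueError("singular fit: parameter covariance undefined")
    ssres = float(np.sum(resid**2))
    return RegressionFit(
        a=a, b=b, covariance=np.asarray(cov),
        r_squared=1.0 - ssres / sstot if sstot > 0 else 0.0,
        n=int(x.size),
        residual_variance=ssres / dof,
    )


def predict_fraction(fit: RegressionFit, x, *, level: float = 0.95):
    """Predicted fraction (percent) with a delta-method confidence band.

    Returns (estimate, lower, upper), all clipped to [0, 100].  Refuses
    x > 1: the regression is not valid below the oxic zone, where
    abundances are elevated at the oxic-anoxic transition.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("prediction is only defined for relative depths in [0, 1]")
    yhat = fit.predict(x)
    # gradient of a*exp(b*x) wrt (a, b)
    g = np.stack([np.exp(fit.b * x), fit.a * x * np.exp(fit.b * x)])
    var = np.einsum("i...,ij,j...->...", g, fit.covariance, g)
    se = np.sqrt(np.maximum(var, 0.0))
    tq = stats.t.ppf(0.5 + level / 2.0, df=max(fit.n - 2, 1))
    lo = np.clip(yhat - tq * se, 0.0, 100.0)
    hi = np.clip(yhat + tq * se, 0.0, 100.0)
    return np.clip(yhat, 0.0, 100.0), lo, hi


def estimate_aoa_absolute(total_cells, fraction_pct, ci_pct=None):
    """AOA cells cm-3 = totals * fraction/100, with multiplicative CI.

    ``ci_pct`` is an optional (lower, upper) fraction band in percent.
    """
    total_cells = np.asarray(total_cells, dtype=float)
    fraction_pct = np.asarray(fraction_pct, dtype=float)
    if np.any(total_cells < 0):
        raise ValueError("total cells must be >= 0")
    if np.any(fraction_pct > 100.0) or np.any(fraction_pct < 0):
        raise ValueError("fractions must lie in [0, 100] percent")
    est = total_cells * fraction_pct / 100.0
    if ci_pct is None:
        return est
    lo, hi = (np.asarray(v, dtype=float) for v in ci_pct)
    return est, total_cells * lo / 100.0, total_cells * hi / 100.0


def compare_with_qpcr(estimated: pd.DataFrame, qpcr: pd.DataFrame):
    """Fold differences between regression-derived and qPCR abundances.

    Both frames need ``depth_m`` plus ``aoa_cells_per_cm3`` (estimated) /
    ``amoa_copies_per_cm3`` (qPCR).  Zero qPCR values are excluded with a
    warning.  Returns (per-depth frame, summary dict with median and max
    fold).
    """
    merged = estimated.merge(qpcr, on="depth_m", suffixes=("_est", "_qpcr"))
    if merged.empty:
        raise ValueError("no overlapping depths between estimate and qPCR")
    zero = merged["amoa_copies_per_cm3"] <= 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero qPCR values")
        merged = merged[~zero]
    est = merged["aoa_cells_per_cm3"].to_numpy()
    q = merged["amoa_copies_per_cm3"].to_numpy()
    fold = np.maximum(est, q) / np.minimum(est, q)
    out = merged[["depth_m"]].copy()
    out["fold_difference"] = fold
    summary = {"median_fold": float(np.median(fold)), "max_fold": float(np.max(fold)),
               "n": int(fold.size)}
    return out, summary
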