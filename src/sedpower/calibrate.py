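"""Weighted least-squares calibration of the diagenetic model.

The original workflow this package formalises tuned parameters by eye
against measured profiles; here the same comparison is cast as a
least-squares problem.  The objective is the per-species model-data
residual normalised by the species' measurement scale (its maximum
measured value), summed over all species present in the data.  Free
parameters may be kinetic constants or the site's organic flux, and are
optimised in log space to respect positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .diagnostics import rmse, validate_measured
from .grid import Grid
from .kinetics import ProfileSet
from .parameters import KineticParameters, SiteConfig
from .solver import SolverError, solve_steady_state

#: site-level parameters the calibrator may vary
_SITE_PARAMS = ("organic_flux",)
_ALIASES = {"F_org": "organic_flux"}


@dataclass
class CalibrationResult:
    params: KineticParameters
    site: SiteConfig
    fitted: dict  # name -> fitted value
    objective: float
    objective_trace: list = field(default_factory=list)
    rmse_by_species: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""


def _apply(site: SiteConfig, p: KineticParameters, names, values):
    site_changes, kin_changes = {}, {}
    for name, value in zip(names, values):
        name = _ALIASES.get(name, name)
        if name in _SITE_PARAMS:
            site_changes[name] = value
        else:
            kin_changes[name] = value
    if site_changes:
        site = site.replace(**site_changes)
    if kin_changes:
        p = p.replace(**kin_changes)
    return site, p


def calibrate(
    site: SiteConfig,
    p0: KineticParameters,
    grid: Grid,
    measured: pd.DataFrame,
    free: tuple,
    *,
    bounds: dict | None = None,
    max_nfev: int = 60,
) -> CalibrationResult:
    """Fit the named free parameters to measured profiles.

    ``free`` lists kinetic parameter names and/or ``"F_org"`` (alias for
    the site's organic flux).  ``bounds`` maps names to (lo, hi); the
    default is a factor of 100 around the starting value.  Residuals are
    (model - data) / scale_s with scale_s the species' maximum measured
    value, so all species weigh comparably.  Solver failures during a
    trial evaluation return a large residual rather than aborting.
    """
    measured = validate_measured(measured)
    free = tuple(free)
    for name in free:
        canonical = _ALIASES.get(name, name)
        if canonical not in _SITE_PARAMS and not hasattr(p0, canonical):
            raise ValueError(f"unknown free parameter {name!r}")

    data = measured[~measured["censored"].astype(bool)]
    scales = {
        sp: max(float(g["value"].max()), 1e-30) for sp, g in data.groupby("species")
    }

    def misfit(site_x: SiteConfig, p_x: KineticParameters, warm):
        profiles, _ = solve_steady_state(site_x, p_x, grid, initial=warm)
        z = profiles.grid.node_depths
        res = []
        for sp, g in data.groupby("species"):
            g = g[g["depth_m"] <= z[-1]]
            if g.empty:
                continue
            if sp == "TOC":
                model = np.interp(g["depth_m"], z, profiles.toc_weight_percent(site_x))
            else:
                model = np.interp(g["depth_m"], z, profiles.solutes[sp])
            res.append((model - g["value"].to_numpy()) / scales[sp])
        return np.concatenate(res), profiles

    if not free:
        resid, _ = misfit(site, p0, None)
        obj = float(np.sum(resid**2))
        return CalibrationResult(
            params=p0, site=site, fitted={}, objective=obj,
            objective_trace=[obj],
            rmse_by_species=rmse(solve_steady_state(site, p0, grid)[0], measured, site),
            message="no free parameters; objective evaluated only",
        )

    x0 = []
    lo, hi = [], []
    for name in free:
        canonical = _ALIASES.get(name, name)
        start = site.organic_flux if canonical in _SITE_PARAMS else getattr(p0, canonical)
        if start <= 0:
            raise ValueError(f"free parameter {name!r} needs a positive start value")
        b = (bounds or {}).get(name, (start / 100.0, start * 100.0))
        if not np.all(np.isfinite(b)):
            raise ValueError(f"bounds for {name!r} must be finite")
        x0.append(np.log(start))
        lo.append(np.log(b[0]))
        hi.append(np.log(b[1]))

    trace: list = []
    warm_cache: dict = {"profiles": None}

    def residual_vec(logx):
        site_x, p_x = _apply(site, p0, free, np.exp(logx))
        try:
            res, profiles = misfit(site_x, p_x, warm_cache["profiles"])
            warm_cache["profiles"] = profiles
        except SolverError:
            res = np.full(max(len(data), 1), 1e3)
        trace.append(float(np.sum(res**2)))
        return res

    sol = least_squares(
        residual_vec, x0, bounds=(lo, hi), method="trf",
        x_scale="jac", diff_step=1e-4, max_nfev=max_nfev,
    )
    fitted_values = np.exp(sol.x)
    site_f, p_f = _apply(site, p0, free, fitted_values)
    profiles_f, _ = solve_steady_state(site_f, p_f, grid)
    return CalibrationResult(
        params=p_f,
        site=site_f,
        fitted=dict(zip(free, map(float, fitted_values))),
        objective=float(2 * sol.cost),
        objective_trace=trace,
        rmse_by_species=rmse(profiles_f, measured, site_f),
        converged=bool(sol.success),
        message=sol.message,
    )
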