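"""Derived quantities and audits on solved profiles.

Oxygen penetration depth, model-data misfit (RMSE), the porewater
NO3-/-O2 slope used as a C/N proxy, element flux budgets, and one-at-a-time
parameter sensitivity scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid
from .kinetics import ProfileSet, RateProfiles, source_terms
from .parameters import SOLUTES, KineticParameters, SiteConfig
from .solver import SolverError, _build_discretisation, solve_steady_state

#: species accepted in measured-profile tables
MEASURABLE = tuple(SOLUTES) + ("TOC",)

BEYOND_DOMAIN = np.inf  # sentinel returned when O2 never falls below threshold


def validate_measured(measured: pd.DataFrame) -> pd.DataFrame:
    """Check a measured-profile table (depth_m, species, value[, sd, censored])."""
    required = {"depth_m", "species", "value"}
    missing = required - set(measured.columns)
    if missing:
        raise ValueError(f"measured table missing columns {sorted(missing)}")
    bad = set(measured["species"]) - set(MEASURABLE)
    if bad:
        raise ValueError(f"unknown species in measured table: {sorted(bad)}")
    if (measured["depth_m"] < 0).any() or (measured["value"] < 0).any():
        raise ValueError("measured depths and values must be >= 0")
    out = measured.copy()
    if "sd" not in out.columns:
        out["sd"] = np.nan
    if "censored" not in out.columns:
        out["censored"] = False
    return out


def oxygen_penetration_depth(profile: ProfileSet, threshold: float = 1e-3) -> float:
    """First depth (m) where O2 falls below ``threshold`` (mol m-3).

    Linear interpolation between nodes; returns ``np.inf`` when oxygen
    persists above the threshold through the whole domain.
    """
    z = profile.grid.node_depths
    o2 = np.asarray(profile.solutes["O2"], dtype=float)
    below = np.nonzero(o2 < threshold)[0]
    if below.size == 0:
        return BEYOND_DOMAIN
    i = int(below[0])
    if i == 0:
        return 0.0
    c0, c1 = o2[i - 1], o2[i]
    return float(z[i - 1] + (c0 - threshold) * (z[i] - z[i - 1]) / (c0 - c1))


def rmse(modeled: ProfileSet, measured: pd.DataFrame, site: SiteConfig) -> dict:
    """Per-species root-mean-square misfit of the model at the measured depths.

    Solutes are compared in mol m-3, TOC in percent dry weight.  Model
    values are linearly interpolated to the measured depths; species whose
    records all fall outside the model domain are skipped with a warning.
    Censored records (below detection) are excluded.
    """
    measured = validate_measured(measured)
    z = modeled.grid.node_depths
    out = {}
    for species, group in measured.groupby("species"):
        group = group[~group["censored"].astype(bool)]
        inside = group[group["depth_m"] <= z[-1]]
        if inside.empty:
            if not group.empty:
                warnings.warn(f"no {species} records inside the model domain; skipped")
            continue
        if species == "TOC":
            model_vals = np.interp(inside["depth_m"], z, modeled.toc_weight_percent(site))
        else:
            model_vals = np.interp(inside["depth_m"], z, modeled.solutes[species])
        resid = model_vals - inside["value"].to_numpy()
        out[species] = float(np.sqrt(np.mean(resid**2)))
    return out


def nitrate_oxygen_slope(profiles, depth_window: tuple[float, float]) -> float:
    """OLS slope of NO3- against -O2 over a depth window (C/N proxy).

    Accepts a :class:`ProfileSet` or a measured table containing both
    species.  Needs at least 3 paired points in the window.
    """
    z0, z1 = depth_window
    if isinstance(profiles, ProfileSet):
        z = profiles.grid.node_depths
        mask = (z >= z0) & (z <= z1)
        o2 = profiles.solutes["O2"][mask]
        no3 = profiles.solutes["NO3"][mask]
    else:
        measured = validate_measured(profiles)
        o2_rec = measured[measured["species"] == "O2"]
        no3_rec = measured[measured["species"] == "NO3"]
        depths = np.intersect1d(o2_rec["depth_m"], no3_rec["depth_m"])
        depths = depths[(depths >= z0) & (depths <= z1)]
        o2 = o2_rec.set_index("depth_m").loc[depths, "value"].to_numpy()
        no3 = no3_rec.set_index("depth_m").loc[depths, "value"].to_numpy()
    if len(o2) < 3:
        raise ValueError("need at least 3 paired NO3/O2 points in the window")
    if np.ptp(o2) == 0:
        return 0.0
    return float(stats.linregress(-np.asarray(o2), np.asarray(no3)).slope)


@dataclass
class BudgetReport:
    """Steady-state element budgets: influx, outflux, net production (all
    mol m-2 yr-1, gas/N2 losses appearing as negative production) and the
    relative closure error |influx - outflux + production| / influx."""

    elements: dict = field(default_factory=dict)

    def closure_error(self, element: str) -> float:
        return self.elements[element]["closure_error"]

    @property
    def max_closure_error(self) -> float:
        return max(v["closure_error"] for v in self.elements.values())


_ELEMENT_SPECIES = {
    "C": {"DIC": 1.0, "G1": 1.0, "G2": 1.0, "G3": 1.0},
    "N": {"NO3": 1.0, "NH4": 1.0},  # organic N added with 1/rCN below
    "O2": {"O2": 1.0},
    "Mn": {"Mn": 1.0, "MnO2": 1.0},
}


def flux_budget(
    solution: tuple[ProfileSet, RateProfiles],
    site: SiteConfig,
    p: KineticParameters,
) -> BudgetReport:
    """Audit conservation of C, N, O2 and Mn on a converged solution.

    For solutes the boundary influx is the diffusive + advective flux at
    the first interior interface (the surface node itself is held at the
    boundary concentration); for solids it is the prescribed deposition
    flux.  At steady state influx - outflux + integrated net production
    vanishes up to discretisation round-off.
    """
    profiles, rates = solution
    grid = profiles.grid
    disc = _build_discretisation(site, p, grid)
    src = source_terms(rates, site)
    cv = grid.control_volumes
    dz = grid.cell_widths

    def solute_terms(s, j):
        c = profiles.solutes[s]
        influx = float(
            -disc.phi_ds[s][0] * (c[1] - c[0]) / dz[0] + disc.adv_sol[0] * c[0]
        )
        outflux = float(disc.w * disc.phi[-1] * c[-1])
        prod = float(np.sum(src[s][1:] * cv[1:]))
        return influx, outflux, prod

    def solid_terms(s, j):
        q = profiles.solids[s]
        influx = float(disc.top_flux[j])
        outflux = float(disc.w * q[-1])
        prod = float(np.sum(src[s] * cv))
        return influx, outflux, prod

    solids_order = ("G1", "G2", "G3", "MnO2")
    report = {}
    for element, weights in _ELEMENT_SPECIES.items():
        weights = dict(weights)
        if element == "N":
            for g in ("G1", "G2", "G3"):
                weights[g] = 1.0 / site.cn_ratio
        influx = outflux = prod = 0.0
        for s, wgt in weights.items():
            if s in profiles.solutes:
                t = solute_terms(s, None)
            else:
                t = solid_terms(s, solids_order.index(s))
            influx += wgt * t[0]
            outflux += wgt * t[1]
            prod += wgt * t[2]
        scale = max(abs(influx), abs(outflux), abs(prod))
        if scale < 1e-18:  # element absent from this configuration
            closure = 0.0
        else:
            closure = abs(influx - outflux + prod) / max(abs(influx), scale)
        report[element] = {
            "influx": influx,
            "outflux": outflux,
            "net_production": prod,
            "closure_error": closure,
        }
    return BudgetReport(elements=report)


@dataclass
class SensitivityResult:
    factor: float
    profiles: ProfileSet | None
    rates: RateProfiles | None
    opd: float | None
    rmse: dict | None
    error: str | None = None


def sensitivity_scan(
    site: SiteConfig,
    p: KineticParameters,
    grid: Grid,
    param_name: str,
    factors,
    *,
    measured: pd.DataFrame | None = None,
) -> list[SensitivityResult]:
    """Re-solve the model with one parameter scaled by each factor.

    Solver failures for individual factors are recorded in the result
    rather than aborting the scan.
    """
    if not hasattr(p, param_name):
        raise ValueError(f"unknown kinetic parameter {param_name!r}")
    results = []
    base = getattr(p, param_name)
    warm: ProfileSet | None = None
    for fac in factors:
        if not fac > 0:
            raise ValueError("factors must be positive")
        p_fac = p.replace(**{param_name: base * fac})
        try:
            profiles, rates = solve_steady_state(site, p_fac, grid, initial=warm)
        except SolverError as exc:
            results.append(SensitivityResult(fac, None, None, None, None, str(exc)))
            continue
        warm = profiles
        err = rmse(profiles, measured, site) if measured is not None else None
        results.append(
            SensitivityResult(fac, profiles, rates, oxygen_penetration_depth(profiles), err)
        )
    return results


def integrated_rate(rates: RateProfiles, grid: Grid, which: str = "R4", mask=None) -> float:
    """Depth-integrated volumetric rate, mol m-2 yr-1 (optionally masked)."""
    r = getattr(rates, which)
    cv = grid.control_volumes
    if mask is not None:
        r = np.where(mask, r, 0.0)
    return float(np.sum(r * cv))
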