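"""End-to-end pipeline: solve -> (calibrate) -> OPD -> energetics -> AOA
abundance -> cell-specific power.

A :class:`RunConfig` (built from a YAML file or a plain dict) names either
a synthetic preset or a full site/kinetics specification, optional
measured data, and run options.  :func:`run_pipeline` executes the stages
in order, records per-stage wall time, and returns a JSON-serialisable
bundle holding every intermediate product.  A failure raises
:class:`PipelineError` naming the stage; previously completed stages stay
in the partial bundle attached to the error.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import aoa, cellpower, energetics
from .calibrate import calibrate
from .diagnostics import flux_budget, oxygen_penetration_depth, rmse
from .grid import ConfigurationError, build_grid
from .io import read_profile_table
from .parameters import KineticParameters, SiteConfig
from .solver import solve_steady_state
from .synthetic import (
    DEFAULT_GRID,
    ScenarioTruth,
    generate_community_observations,
    make_site_preset,
    total_cells,
)

_RUN_DEFAULTS = dict(
    tolerance=1e-8,
    electron_equivalents=8,
    opd_threshold=1e-3,
    ionic_strength=energetics.DEFAULT_IONIC_STRENGTH,
    n_community_samples=40,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, partial: dict):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.partial = partial


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    preset: str | None = None
    seed: int = 0
    site: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    run: dict = field(default_factory=dict)
    community: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)

    _SECTIONS = ("preset", "seed", "site", "kinetics", "grid", "run",
                 "community", "data", "calibration")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls._SECTIONS)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        unknown_run = set(cfg.run) - set(_RUN_DEFAULTS)
        if unknown_run:
            raise ConfigurationError(f"unknown run options: {sorted(unknown_run)}")
        unknown_data = set(cfg.data) - {"profiles", "community"}
        if unknown_data:
            raise ConfigurationError(f"unknown data keys: {sorted(unknown_data)}")
        if cfg.preset is None and not cfg.site:
            raise ConfigurationError("either a preset or a full site section is required")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        """Plain-dict copy with all defaults filled in (for reproducibility)."""
        run = dict(_RUN_DEFAULTS)
        run.update(self.run)
        grid = dict(DEFAULT_GRID)
        grid.update(self.grid)
        return {
            "preset": self.preset,
            "seed": self.seed,
            "site": dict(self.site),
            "kinetics": dict(self.kinetics),
            "grid": grid,
            "run": run,
            "community": dict(self.community),
            "data": dict(self.data),
            "calibration": dict(self.calibration),
        }


def _build_model(cfg: RunConfig):
    if cfg.preset is not None:
        site, params = make_site_preset(cfg.preset)
        if cfg.site:
            site = site.replace(**cfg.site)
    else:
        site = SiteConfig(**cfg.site)
        params = KineticParameters()
    if cfg.kinetics:
        params = params.replace(**cfg.kinetics)
    g = cfg.resolved()["grid"]
    grid = build_grid(site.domain_length, g["n_nodes"], g["refinement_factor"])
    return site, params, grid


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the result bundle."""
    resolved = config.resolved()
    run = resolved["run"]
    bundle: dict = {"config": resolved, "stages": {}, "log": []}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, str(exc), bundle) from exc
            bundle["log"].append({"stage": name, "seconds": time.perf_counter() - t0})
            return out

        return wrap

    site, params, grid = stage("configure")(lambda: _build_model(config))

    if config.calibration:
        if "profiles" not in config.data:
            raise PipelineError("calibrate", "calibration needs data.profiles", bundle)
        measured = stage("read-profiles")(lambda: read_profile_table(config.data["profiles"]))
        result = stage("calibrate")(
            lambda: calibrate(
                site, params, grid, measured,
                tuple(config.calibration.get("free", ())),
                bounds=config.calibration.get("bounds"),
            )
        )
        site, params = result.site, result.params
        bundle["stages"]["calibration"] = {
            "fitted": result.fitted,
            "objective": result.objective,
            "converged": result.converged,
            "rmse": result.rmse_by_species,
        }

    profiles, rates = stage("solve")(
        lambda: solve_steady_state(site, params, grid, tol=run["tolerance"])
    )
    budget = stage("budget")(lambda: flux_budget((profiles, rates), site, params))
    opd = oxygen_penetration_depth(profiles, run["opd_threshold"])
    z = grid.node_depths
    bundle["stages"]["solve"] = {
        "depth_m": z,
        "solutes": {k: v for k, v in profiles.solutes.items()},
        "solids": {k: v for k, v in profiles.solids.items()},
        "toc_percent_dw": profiles.toc_weight_percent(site),
        "rates": {k: getattr(rates, k) for k in ("R1", "R2", "R3", "R4", "R5", "R6")},
        "opd_m": opd,
        "budget": budget.elements,
    }
    if "profiles" in config.data and not config.calibration:
        measured = stage("read-profiles")(lambda: read_profile_table(config.data["profiles"]))
        bundle["stages"]["solve"]["rmse"] = rmse(profiles, measured, site)

    thermo = stage("energetics")(
        lambda: energetics.gibbs_energy_profile(
            profiles, site,
            electron_equivalents=run["electron_equivalents"],
            ionic_strength=run["ionic_strength"],
            oxic_threshold=run["opd_threshold"],
        )
    )
    power = stage("power")(lambda: energetics.power_supply_profile(thermo, rates))
    bundle["stages"]["energetics"] = {
        "dg0_kj_mol": thermo.dg0,
        "n_e": thermo.n_e,
        "dg_per_e_kj": thermo.dg_per_e,
        "q": thermo.q,
        "ps_w_m3": power.ps,
    }

    # community observations: measured file, or synthetic draws from the
    # scenario truth carried by the preset
    truth = ScenarioTruth(
        site=site, params=params, grid=grid, profiles=profiles, rates=rates,
        community=_community_truth(config), seed=config.seed,
    )
    if "community" in config.data:
        community = stage("read-community")(
            lambda: pd.read_csv(config.data["community"], comment="#")
        )
    else:
        community = stage("community")(
            lambda: generate_community_observations(
                truth, run["n_community_samples"], config.seed, opd=None
            )
        )

    def fit_stage():
        x = aoa.relative_depth(community["depth_m"], community["opd_m"].iloc[0])
        keep = x <= 1.0
        return aoa.fit_exponential_decay(x[keep], community["aoa_fraction_pct"][keep])

    fit = stage("fit-aoa")(fit_stage)
    bundle["stages"]["aoa_fit"] = {
        "a_pct": fit.a, "b": fit.b, "r_squared": fit.r_squared, "n": fit.n,
        "covariance": fit.covariance,
    }

    def abundance_stage():
        finite_opd = opd if np.isfinite(opd) else grid.length
        mask = (z <= finite_opd) & np.asarray(thermo.oxic_mask)
        x = z[mask] / finite_opd
        frac, lo, hi = aoa.predict_fraction(fit, np.clip(x, 0.0, 1.0))
        totals = total_cells(truth, z[mask])
        est, est_lo, est_hi = aoa.estimate_aoa_absolute(totals, frac, (lo, hi))
        return pd.DataFrame(
            {
                "depth_m": z[mask], "x": x, "fraction_pct": frac,
                "total_cells_per_cm3": totals,
                "aoa_cells_per_cm3": est,
                "aoa_lo": est_lo, "aoa_hi": est_hi,
                "ps_w_m3": np.asarray(power.ps)[mask],
            }
        )

    abundance = stage("abundance")(abundance_stage)

    def cellpower_stage():
        p, p_lo, p_hi = cellpower.cell_specific_power(
            abundance["ps_w_m3"], abundance["aoa_cells_per_cm3"],
            (abundance["aoa_lo"], abundance["aoa_hi"]),
        )
        out = abundance.copy()
        out["p_cell_w"] = p
        out["p_cell_lo_w"] = p_lo
        out["p_cell_hi_w"] = p_hi
        return out

    cp = stage("cell-power")(cellpower_stage)
    summary = stage("summarize")(lambda: cellpower.summarize_cell_power(cp))
    bundle["stages"]["cell_power"] = {
        "table": {k: cp[k].to_numpy() for k in cp.columns},
        "bins": {k: summary.table[k].to_numpy() for k in summary.table.columns},
        "increases_with_depth": summary.increases_with_depth,
    }
    return bundle


def _community_truth(cfg: RunConfig) -> dict:
    from .synthetic import _COMMUNITY_DEFAULTS, _PRESETS

    truth = dict(_COMMUNITY_DEFAULTS)
    if cfg.preset is not None:
        key = cfg.preset if cfg.preset in _PRESETS else f"{cfg.preset}-like"
        truth.update(_PRESETS[key]["community"])
    else:
        truth.setdefault("n0", 1e7)
    truth.update(cfg.community)
    return truth
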