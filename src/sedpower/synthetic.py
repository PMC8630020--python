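"""Synthetic sediment sites with known ground truth.

Five presets emulate the range of open-ocean oxic sediments the pipeline
is designed for, spanning >3 orders of magnitude in organic-matter flux
and oxygen penetration depth: a productive Arabian Sea-type site
(SAST-like), a ridge-flank site (AMOR-like), and three oligotrophic gyre
sites (NP-like, NPG-like, SPG-like) whose modeled domain stays fully oxic.
Water depths and sedimentation rates follow the published site table; the
kinetic parameters are package defaults chosen once to reproduce each
regime's oxygen penetration scale.

The generators add multiplicative lognormal noise to geochemical profiles
(with a 0.1 uM detection limit on the N species, below which records are
left-censored) and lognormal scatter to community observations, so every
pipeline stage can be exercised against retained truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ConfigurationError, Grid, build_grid
from .kinetics import ProfileSet, RateProfiles
from .parameters import KineticParameters, SiteConfig
from .solver import solve_steady_state

#: detection limit of the colorimetric nutrient analysis, mol m-3 (0.1 uM)
DETECTION_LIMIT = 1e-4
_CENSORED_SPECIES = ("NO3", "NH4")

#: default grid used for preset solves
DEFAULT_GRID = {"n_nodes": 150, "refinement_factor": 1.04}

_PRESETS = {
    "SAST-like": dict(
        site=dict(
            name="SAST-like",
            water_depth=4424.0,
            temperature=1.5,
            pH=7.79,
            sedimentation_rate=1.2e-5,
            domain_length=0.4,
            top_concentrations={"O2": 0.20, "NO3": 0.035, "NH4": 1e-5, "Mn": 0.0, "DIC": 2.3},
            organic_flux=0.24,
            fully_oxic=False,
        ),
        kinetics=dict(k1=4e-4, k2=1e-5),
        community=dict(n0=3e8),
    ),
    "AMOR-like": dict(
        site=dict(
            name="AMOR-like",
            water_depth=2476.0,
            temperature=-0.5,
            pH=7.79,
            sedimentation_rate=2.0e-5,
            domain_length=10.0,
            top_concentrations={"O2": 0.30, "NO3": 0.015, "NH4": 1e-5, "Mn": 0.0, "DIC": 2.3},
            organic_flux=0.012,
            fully_oxic=False,
        ),
        kinetics=dict(k1=3e-5, k2=3e-7),
        community=dict(n0=1e8),
    ),
    "NP-like": dict(
        site=dict(
            name="NP-like",
            water_depth=4476.0,
            temperature=2.5,
            pH=7.79,
            sedimentation_rate=9.4e-6,
            domain_length=30.0,
            top_concentrations={"O2": 0.25, "NO3": 0.022, "NH4": 1e-5, "Mn": 0.0, "DIC": 2.3},
            organic_flux=1.2e-3,
            fully_oxic=True,
        ),
        kinetics=dict(k1=1e-5, k2=1e-7),
        community=dict(n0=1e7),
    ),
    "NPG-like": dict(
        site=dict(
            name="NPG-like",
            water_depth=6000.0,
            temperature=1.5,
            pH=7.79,
            sedimentation_rate=1.0e-6,
            domain_length=20.0,
            top_concentrations={"O2": 0.21, "NO3": 0.040, "NH4": 1e-5, "Mn": 0.0, "DIC": 2.3},
            organic_flux=5e-4,
            fully_oxic=True,
        ),
        kinetics=dict(k1=1e-5, k2=1e-7),
        community=dict(n0=2e6),
    ),
    "SPG-like": dict(
        site=dict(
            name="SPG-like",
            water_depth=5075.0,
            temperature=1.3,
            pH=7.79,
            sedimentation_rate=1.5e-6,
            domain_length=67.0,
            top_concentrations={"O2": 0.21, "NO3": 0.033, "NH4": 1e-5, "Mn": 0.0, "DIC": 2.3},
            organic_flux=1.4e-4,
            fully_oxic=True,
        ),
        kinetics=dict(k1=1e-5, k2=1e-7),
        community=dict(n0=5e5),
    ),
}

#: community-truth defaults shared by all presets: surface AOA fraction a
#: (percent), decay b per unit relative depth, lognormal fraction scatter,
#: total-cell power-law exponent m with reference depth z0, and qPCR scatter
_COMMUNITY_DEFAULTS = dict(a=22.3, b=-2.0, sigma_frac=0.5, m=0.7, z0=0.01, sigma_log10=0.3)


def preset_names() -> list[str]:
    return list(_PRESETS)


def make_site_preset(name: str) -> tuple[SiteConfig, KineticParameters]:
    """Return the site configuration and kinetics of a named preset."""
    key = name if name in _PRESETS else f"{name}-like"
    if key not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        )
    entry = _PRESETS[key]
    return SiteConfig(**entry["site"]), KineticParameters(**entry["kinetics"])


@dataclass
class ScenarioTruth:
    """A fully specified synthetic site: configuration, noiseless solution
    and the community ground truth used by the observation generators."""

    site: SiteConfig
    params: KineticParameters
    grid: Grid
    profiles: ProfileSet
    rates: RateProfiles
    community: dict = field(default_factory=dict)
    seed: int | None = None


def make_scenario(
    preset: str,
    seed: int | None = None,
    *,
    n_nodes: int | None = None,
    refinement_factor: float | None = None,
    community: dict | None = None,
) -> ScenarioTruth:
    """Solve a preset and bundle it with community ground truth."""
    site, params = make_site_preset(preset)
    grid = build_grid(
        site.domain_length,
        n_nodes or DEFAULT_GRID["n_nodes"],
        refinement_factor or DEFAULT_GRID["refinement_factor"],
    )
    profiles, rates = solve_steady_state(site, params, grid)
    key = preset if preset in _PRESETS else f"{preset}-like"
    comm = dict(_COMMUNITY_DEFAULTS)
    comm.update(_PRESETS[key]["community"])
    comm.update(community or {})
    return ScenarioTruth(
        site=site, params=params, grid=grid, profiles=profiles, rates=rates,
        community=comm, seed=seed,
    )


def generate_observations(
    truth: ScenarioTruth,
    n_depths: int,
    noise_cv: float,
    seed: int,
    species: tuple = ("O2", "NO3", "NH4", "DIC", "TOC"),
    detection_limit: float = DETECTION_LIMIT,
) -> pd.DataFrame:
    """Sample noisy measured profiles from a solved scenario.

    Depths are stratified-random in the grid's node-index coordinate, so
    sampling is densest near the surface where gradients are steepest --
    mirroring how porewater profiles are actually sampled.  Values carry
    multiplicative lognormal noise with coefficient of variation
    ``noise_cv``; NO3 and NH4 below ``detection_limit`` (mol m-3; 0 to
    disable) become left-censored records at the limit.
    """
    if n_depths < 4:
        raise ConfigurationError("need at least 4 sampling depths")
    rng = np.random.default_rng(seed)
    z = truth.grid.node_depths
    idx_edges = np.linspace(0.0, z.size - 1, n_depths + 1)
    u = rng.uniform(idx_edges[:-1], idx_edges[1:])
    depths = np.interp(u, np.arange(z.size), z)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    records = []
    for sp in species:
        if sp == "TOC":
            profile = truth.profiles.toc_weight_percent(truth.site)
        else:
            profile = truth.profiles.solutes[sp]
        vals = np.interp(depths, z, profile)
        if sigma > 0:
            vals = vals * np.exp(rng.normal(0.0, sigma, size=vals.shape))
        for d, v in zip(depths, vals):
            censored = sp in _CENSORED_SPECIES and v < detection_limit
            records.append(
                {
                    "site": truth.site.name,
                    "depth_m": float(d),
                    "species": sp,
                    "value": detection_limit if censored else float(v),
                    "sd": np.nan,
                    "censored": censored,
                }
            )
    return pd.DataFrame.from_records(records)


def total_cells(truth: ScenarioTruth, depths) -> np.ndarray:
    """Power-law total-cell profile N(z) = N0 (max(z, z0)/z0)^-m, cells cm-3."""
    c = truth.community
    z = np.maximum(np.asarray(depths, dtype=float), c["z0"])
    return c["n0"] * (z / c["z0"]) ** (-c["m"])


def generate_community_observations(
    truth: ScenarioTruth,
    n_samples: int,
    seed: int,
    *,
    opd: float | None = None,
) -> pd.DataFrame:
    """Sample community observations (AOA fraction, totals, qPCR) in the oxic zone.

    The AOA fraction follows a*exp(b*x) in relative depth x = z/OPD with
    lognormal scatter sigma_frac; total cells decline as a power law of
    depth; amoA qPCR copies are fraction*totals with 10^N(0, sigma_log10)
    scatter.
    """
    if n_samples < 5:
        raise ConfigurationError("need at least 5 community samples")
    from .diagnostics import oxygen_penetration_depth

    c = truth.community
    if opd is None:
        opd = oxygen_penetration_depth(truth.profiles)
    if not np.isfinite(opd):
        opd = truth.grid.length  # fully oxic: the whole domain is the oxic zone
    rng = np.random.default_rng(seed)
    depths = np.sort(rng.uniform(0.0, opd, size=n_samples))
    x = depths / opd
    frac = c["a"] * np.exp(c["b"] * x)
    if c["sigma_frac"] > 0:
        frac = frac * np.exp(rng.normal(0.0, c["sigma_frac"], size=n_samples))
    frac = np.clip(frac, 0.0, 100.0)
    totals = total_cells(truth, depths)
    copies = frac / 100.0 * totals
    if c["sigma_log10"] > 0:
        copies = copies * 10.0 ** rng.normal(0.0, c["sigma_log10"], size=n_samples)
    return pd.DataFrame(
        {
            "core": truth.site.name,
            "depth_m": depths,
            "opd_m": opd,
            "aoa_fraction_pct": frac,
            "total_cells_per_cm3": totals,
            "amoa_copies_per_cm3": copies,
        }
    )
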