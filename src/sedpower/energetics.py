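"""Gibbs energy and power supply of nitrification along model profiles.

The catabolic reaction is written on the ammonia form of the substrate,

    NH3 + 2 O2(aq) -> NO3- + H+ + H2O        (8 electrons transferred)

and its in situ energy yield is

    dGr = dGr0(T, P) + R T ln Qr,   Qr = prod(a_i^nu_i)

with activities a_i = gamma_i * m_i from an extended Debye-Hueckel model at
seawater ionic strength.  dGr0 is moved from the 25 C, 1 bar reference to in
situ conditions by the van 't Hoff relation (constant reaction enthalpy)
plus a constant-volume pressure term; this captures the dominant T and P
dependence at the few-kJ level without a full equation of state.  NH3 is
obtained from modeled NH4+ via the pH-dependent acid-base equilibrium,
[NH3] = [NH4+] * 10^(pH - pKa), pKa = 9.3.

Energies are reported per mole of electrons transferred.  The default
divides by the full 8-electron stoichiometry; a 4-electron-equivalent
convention is also supported for comparison with published per-electron
figures that imply it.  The volumetric power supply Ps (W m-3) is the
product of the per-reaction energy yield magnitude and the nitrification
rate, and is therefore independent of the electron convention.

Calculations are restricted to the oxic zone (O2 >= 1 uM by default);
depths below it carry NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .grid import ConfigurationError
from .kinetics import ProfileSet, RateProfiles
from .parameters import SiteConfig
from .units import GAS_CONSTANT, SECONDS_PER_YEAR, celsius_to_kelvin

DEFAULT_PKA = 9.3
DEFAULT_IONIC_STRENGTH = 0.7  # mol kg-1, seawater
OXIC_THRESHOLD = 1e-3  # mol m-3 (1 uM)

# Debye-Hueckel limiting-law coefficients, linear in temperature over the
# 0-35 C range relevant to deep-sea sediments (A in kg^0.5 mol^-0.5,
# B in kg^0.5 mol^-0.5 Angstrom^-1)
_DH_A = (0.4918, (0.5092 - 0.4918) / 25.0)
_DH_B = (0.3248, (0.3283 - 0.3248) / 25.0)

T_REF = 298.15  # K
P_REF = 1.0  # bar


@dataclass(frozen=True)
class Reaction:
    """Stoichiometry (positive products, negative reactants) + electrons."""

    stoichiometry: dict
    n_electrons: int
    name: str = ""


NITRIFICATION_NH3 = Reaction(
    stoichiometry={"NH3": -1, "O2": -2, "NO3-": 1, "H+": 1, "H2O": 1},
    n_electrons=8,
    name="nitrification (NH3 basis)",
)


@dataclass(frozen=True)
class ThermoTable:
    """Per-species standard-state properties at 25 C / 1 bar."""

    dgf: dict  # kJ mol-1
    dhf: dict  # kJ mol-1
    charge: dict
    ion_size: dict  # Angstrom
    volume: dict  # cm3 mol-1

    def check_covers(self, reaction: Reaction):
        missing = [s for s in reaction.stoichiometry if s not in self.dgf]
        if missing:
            raise ConfigurationError(f"thermo table missing species {missing}")


def load_thermo_table(path=None) -> ThermoTable:
    """Load the packaged thermo table, or a user CSV with the same columns."""
    if path is None:
        ref = resources.files("sedpower").joinpath("data/thermo_nitrification.csv")
        with resources.as_file(ref) as fp:
            df = pd.read_csv(fp, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    df = df.set_index("species")
    return ThermoTable(
        dgf=df["dGf_kJ_mol"].to_dict(),
        dhf=df["dHf_kJ_mol"].to_dict(),
        charge=df["charge"].to_dict(),
        ion_size=df["ion_size_A"].to_dict(),
        volume=df["volume_cm3_mol"].to_dict(),
    )


def nh3_from_nh4(nh4, pH: float, pKa: float = DEFAULT_PKA):
    """Free ammonia from total ammonium via the acid-base equilibrium."""
    nh4 = np.asarray(nh4, dtype=float)
    if np.any(nh4 < 0):
        raise ValueError("NH4+ concentrations must be >= 0")
    return nh4 * 10.0 ** (pH - pKa)


def debye_huckel_coefficients(temperature_k: float) -> tuple[float, float]:
    t_c = temperature_k - 273.15
    return _DH_A[0] + _DH_A[1] * t_c, _DH_B[0] + _DH_B[1] * t_c


def activity_coefficient(charge, ionic_strength, temperature_k, ion_size):
    """Extended Debye-Hueckel activity coefficient.

    log10 gamma = -A z^2 sqrt(I) / (1 + B a sqrt(I)); neutral species
    return exactly 1.
    """
    if np.any(np.asarray(ionic_strength) < 0):
        raise ValueError("ionic strength must be >= 0")
    if charge == 0:
        return np.ones_like(np.asarray(ionic_strength, dtype=float)) * 1.0
    a, b = debye_huckel_coefficients(temperature_k)
    sqrt_i = np.sqrt(ionic_strength)
    log_gamma = -a * charge**2 * sqrt_i / (1.0 + b * ion_size * sqrt_i)
    return 10.0**log_gamma


def standard_gibbs(
    reaction: Reaction,
    table: ThermoTable,
    temperature_k: float,
    pressure_bar: float = P_REF,
) -> float:
    """dGr0 at in situ T and P, kJ per mole of reaction turnover.

    van 't Hoff temperature correction (constant reaction enthalpy) plus
    a constant reaction-volume pressure term dV (P - 1 bar).
    """
    table.check_covers(reaction)
    nu = reaction.stoichiometry
    dg298 = sum(v * table.dgf[s] for s, v in nu.items())
    dh298 = sum(v * table.dhf[s] for s, v in nu.items())
    ds298 = (dh298 - dg298) / T_REF  # kJ mol-1 K-1
    dg_t = dh298 - temperature_k * ds298
    dv = sum(v * table.volume[s] for s, v in nu.items())  # cm3 mol-1
    # cm3 -> m3 (1e-6), bar -> Pa (1e5), J -> kJ (1e-3)
    dg_p = dv * 1e-6 * (pressure_bar - P_REF) * 1e5 * 1e-3
    return dg_t + dg_p


@dataclass
class ThermoResult:
    """Per-depth thermodynamic state of the nitrification reaction."""

    depth: np.ndarray
    temperature_k: float
    pressure_bar: float
    ionic_strength: float
    activities: dict  # species -> molal activity (NaN below the oxic zone)
    gammas: dict
    q: np.ndarray
    dg0: float  # kJ per mol reaction
    dg_per_e: np.ndarray  # kJ per mol electron
    n_e: int
    oxic_mask: np.ndarray
    reaction: Reaction = field(default=NITRIFICATION_NH3, repr=False)


def gibbs_energy_profile(
    profiles: ProfileSet,
    site: SiteConfig,
    table: ThermoTable | None = None,
    *,
    reaction: Reaction = NITRIFICATION_NH3,
    electron_equivalents: int | None = None,
    ionic_strength: float = DEFAULT_IONIC_STRENGTH,
    pKa: float = DEFAULT_PKA,
    oxic_threshold: float = OXIC_THRESHOLD,
) -> ThermoResult:
    """In situ Gibbs energy of nitrification along a solved profile.

    ``electron_equivalents`` defaults to the reaction's stoichiometric
    electron number (8); pass 4 for the 4-electron-equivalent convention.
    Depths outside the oxic zone, or with non-positive substrate activity,
    are NaN-masked.
    """
    if table is None:
        table = load_thermo_table()
    table.check_covers(reaction)
    n_e = electron_equivalents or reaction.n_electrons
    if n_e not in (4, 8):
        raise ConfigurationError("electron_equivalents must be 4 or 8")
    t_k = float(celsius_to_kelvin(site.temperature))
    p_bar = site.hydrostatic_pressure()
    z = profiles.grid.node_depths
    o2 = profiles.solutes["O2"]
    oxic = o2 >= oxic_threshold

    # molal concentrations (mol m-3 porewater ~ mmol/kg -> /1000)
    molal = {
        "O2": o2 / 1000.0,
        "NO3-": profiles.solutes["NO3"] / 1000.0,
        "NH3": nh3_from_nh4(profiles.solutes["NH4"], site.pH, pKa) / 1000.0,
        "H+": np.full_like(o2, 10.0 ** (-site.pH)),
        "H2O": np.ones_like(o2),
    }
    gammas = {}
    activities = {}
    for s in reaction.stoichiometry:
        if s == "H2O":
            gammas[s] = np.ones_like(o2)
            activities[s] = np.ones_like(o2)  # a(H2O) = 1 by convention
        elif s == "H+":
            gammas[s] = np.ones_like(o2)
            activities[s] = molal[s]  # pH already measures H+ activity
        else:
            g = activity_coefficient(table.charge[s], ionic_strength, t_k, table.ion_size[s])
            gammas[s] = np.full_like(o2, g)
            activities[s] = molal[s] * g

    defined = oxic.copy()
    for s, nu in reaction.stoichiometry.items():
        if nu < 0:  # reactant activity must be positive
            defined &= activities[s] > 0

    ln_q = np.full_like(o2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = np.zeros_like(o2)
        for s, nu in reaction.stoichiometry.items():
            acc = acc + nu * np.log(np.where(activities[s] > 0, activities[s], np.nan))
    ln_q[defined] = acc[defined]

    dg0 = standard_gibbs(reaction, table, t_k, p_bar)
    dg_per_e = (dg0 + GAS_CONSTANT * t_k * ln_q / 1000.0) / n_e

    for s in activities:
        activities[s] = np.where(defined, activities[s], np.nan)
    return ThermoResult(
        depth=z,
        temperature_k=t_k,
        pressure_bar=p_bar,
        ionic_strength=ionic_strength,
        activities=activities,
        gammas=gammas,
        q=np.exp(ln_q),
        dg0=dg0,
        dg_per_e=dg_per_e,
        n_e=n_e,
        oxic_mask=defined,
        reaction=reaction,
    )


@dataclass
class PowerProfile:
    """Volumetric power supply of nitrification."""

    depth: np.ndarray
    rate: np.ndarray  # mol N m-3 yr-1
    ps: np.ndarray  # W m-3, positive magnitude convention
    oxic_mask: np.ndarray


def power_supply_profile(thermo: ThermoResult, rates: RateProfiles) -> PowerProfile:
    """Ps = |dGr| * R4, converted from kJ m-3 yr-1 to W m-3.

    The per-reaction energy (dg_per_e * n_e) multiplies the nitrification
    rate in mol N m-3 yr-1 (one reaction turnover per N); Ps is reported
    as a positive magnitude, zero where the rate is zero, NaN outside the
    oxic zone.
    """
    r4 = np.asarray(rates.R4, dtype=float)
    if r4.shape != thermo.depth.shape:
        raise ValueError("rate and thermodynamic grids do not match")
    energy_per_mol = np.abs(thermo.dg_per_e) * thermo.n_e  # kJ per mol N
    ps = energy_per_mol * r4 * 1e3 / SECONDS_PER_YEAR
    ps = np.where(r4 == 0.0, 0.0, ps)
    ps = np.where(thermo.oxic_mask, ps, np.nan)
    return PowerProfile(depth=thermo.depth, rate=r4, ps=ps, oxic_mask=thermo.oxic_mask)
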