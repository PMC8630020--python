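"""Unit conventions and conversions used throughout the package.

Internal units
--------------
depth            m, positive down, sediment-water interface at 0
solutes          mol m-3 of porewater
solids           mol m-3 of bulk sediment
rates            mol m-3 of bulk sediment yr-1
diffusivities    m2 yr-1
fluxes           mol m-2 yr-1 (positive into the sediment)
temperature      degrees C in configuration, Kelvin in thermodynamics
energy           kJ mol-1; power W m-3 or W cell-1
"""

from __future__ import annotations

import numpy as np

SECONDS_PER_YEAR = 3.1536e7
GAS_CONSTANT = 8.314  # J mol-1 K-1
CELSIUS_OFFSET = 273.15
MOLAR_MASS_C = 12.011  # g mol-1

#: conversion factors to mol m-3 for the tabular-profile readers
_CONCENTRATION_FACTORS = {
    "uM": 1e-3,
    "umol/L": 1e-3,
    "mmol/L": 1.0,
    "mM": 1.0,
    "mol/m3": 1.0,
}


def concentration_to_si(value, unit: str):
    """Convert a concentration in a supported unit to mol m-3."""
    try:
        return np.asarray(value, dtype=float) * _CONCENTRATION_FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unsupported concentration unit {unit!r}; "
            f"supported: {sorted(_CONCENTRATION_FACTORS)} or 'percent_dw' for TOC"
        ) from None


def toc_molar_to_weight_percent(toc_mol_m3_bulk, porosity, dry_density_g_cm3):
    """Convert organic carbon in mol C m-3 bulk to percent dry weight.

    Solid mass per m3 of bulk sediment is (1 - phi) * rho_s; rho_s is in
    g cm-3 = 1e6 g m-3.
    """
    solid_mass = (1.0 - np.asarray(porosity)) * dry_density_g_cm3 * 1e6  # g m-3
    return 100.0 * np.asarray(toc_mol_m3_bulk) * MOLAR_MASS_C / solid_mass


def toc_weight_percent_to_molar(toc_pct_dw, porosity, dry_density_g_cm3):
    """Inverse of :func:`toc_molar_to_weight_percent`."""
    solid_mass = (1.0 - np.asarray(porosity)) * dry_density_g_cm3 * 1e6
    return np.asarray(toc_pct_dw) / 100.0 * solid_mass / MOLAR_MASS_C


def celsius_to_kelvin(t_celsius):
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET
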