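"""Site configuration, kinetic parameters and transport coefficients.

A :class:`SiteConfig` describes one sediment core: geometry, physics,
boundary conditions and the metadata (water depth, temperature,
sedimentation rate) that feed the thermodynamic calculations.  A
:class:`KineticParameters` bundle holds the multi-G reactivities,
Monod/inhibition constants and bimolecular rate constants of the reaction
network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .grid import ConfigurationError

SOLUTES = ("O2", "NO3", "NH4", "Mn", "DIC")
SOLIDS = ("G1", "G2", "G3", "MnO2")

# Linear temperature fits to infinite-dilution tracer diffusivities,
# D0 = (a + b * T[degC]) * 1e-6 cm2 s-1, after the standard compilations
# used in early-diagenesis modelling.
_D0_COEFFS = {  # (a, b) in 1e-6 cm2 s-1
    "O2": (11.70, 0.344),
    "NO3": (9.72, 0.365),
    "NH4": (9.76, 0.398),
    "Mn": (3.04, 0.153),
    "DIC": (5.06, 0.275),  # bicarbonate dominates DIC at seawater pH
}
_CM2_S_TO_M2_YR = 1e-4 * 3.1536e7  # 1 cm2 s-1 in m2 yr-1


def molecular_diffusivity(species: str, temperature_c: float) -> float:
    """Free-solution diffusivity D0 of a solute in m2 yr-1 at T in deg C."""
    try:
        a, b = _D0_COEFFS[species]
    except KeyError:
        raise ConfigurationError(f"no diffusivity coefficients for {species!r}") from None
    return (a + b * temperature_c) * 1e-6 * _CM2_S_TO_M2_YR


def effective_transport(d0, temperature_c: float, porosity, temp_slope: float = 0.0):
    """Sediment diffusivity Ds = D0(T) / theta^2 with theta^2 = 1 - 2 ln(phi).

    ``d0`` is the free-solution diffusivity at 0 deg C (m2 yr-1);
    ``temp_slope`` is its fractional increase per deg C, so
    D0(T) = d0 * (1 + temp_slope * T).  The tortuosity correction uses the
    porosity array; porosity must lie in (0, 1].
    """
    phi = np.asarray(porosity, dtype=float)
    if np.any(phi <= 0) or np.any(phi > 1):
        raise ConfigurationError("porosity must lie in (0, 1]")
    if np.any(np.asarray(d0) <= 0):
        raise ConfigurationError("d0 must be positive")
    theta2 = 1.0 - 2.0 * np.log(phi)
    return np.asarray(d0) * (1.0 + temp_slope * temperature_c) / theta2


@dataclass(frozen=True)
class SiteConfig:
    """Geometry, physics and boundary conditions of one sediment core."""

    name: str
    water_depth: float  # m
    temperature: float  # deg C
    pH: float
    sedimentation_rate: float  # m yr-1 (w, burial advection)
    domain_length: float  # m
    top_concentrations: dict  # species -> mol m-3 at z = 0
    organic_flux: float  # mol C m-2 yr-1 across the interface
    g_fractions: tuple = (0.5, 0.3, 0.2)  # (f1, f2, f3), sum 1
    cn_ratio: float = 106.0 / 16.0  # mol C per mol N (Redfield default)
    porosity_surface: float = 0.85
    porosity_deep: float = 0.75
    porosity_attenuation: float = 1.0  # m-1
    dry_density: float = 2.65  # g cm-3
    mno2_flux: float = 0.0  # mol Mn m-2 yr-1 deposited at the interface
    pressure: float | None = None  # bar; hydrostatic default
    fully_oxic: bool = False  # disables R3, R5, R6

    def __post_init__(self):
        if not self.domain_length > 0:
            raise ConfigurationError("domain_length must be positive")
        f = self.g_fractions
        if len(f) != 3 or abs(sum(f) - 1.0) > 1e-12 or any(x < 0 for x in f):
            raise ConfigurationError("g_fractions must be 3 non-negative values summing to 1")
        if not (0 < self.porosity_deep <= self.porosity_surface < 1):
            raise ConfigurationError("require 0 < porosity_deep <= porosity_surface < 1")
        if not self.cn_ratio > 0:
            raise ConfigurationError("cn_ratio must be positive")
        if self.sedimentation_rate < 0:
            raise ConfigurationError("sedimentation_rate must be >= 0")
        missing = [s for s in SOLUTES if s not in self.top_concentrations]
        if missing:
            raise ConfigurationError(f"top_concentrations missing {missing}")
        if any(v < 0 for v in self.top_concentrations.values()):
            raise ConfigurationError("top concentrations must be >= 0")
        if self.organic_flux < 0 or self.mno2_flux < 0:
            raise ConfigurationError("boundary fluxes must be >= 0")
        if (self.organic_flux > 0 or self.mno2_flux > 0) and self.sedimentation_rate == 0:
            raise ConfigurationError(
                "a solid deposition flux with zero burial velocity has no steady state"
            )

    def porosity_profile(self, depths) -> np.ndarray:
        """Exponential compaction profile phi(z) = phi_inf + (phi_0 - phi_inf) e^(-beta z)."""
        z = np.asarray(depths, dtype=float)
        return self.porosity_deep + (self.porosity_surface - self.porosity_deep) * np.exp(
            -self.porosity_attenuation * z
        )

    def hydrostatic_pressure(self) -> float:
        """In situ pressure in bar (1 bar at surface + ~1 bar per 10 m water)."""
        if self.pressure is not None:
            return self.pressure
        return 1.0 + self.water_depth / 10.0

    def replace(self, **changes) -> "SiteConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class KineticParameters:
    """Reactivities and rate constants of the diagenetic reaction network.

    The organic matter is split into three pools: G1 (labile, reactivity
    k1), G2 (less reactive, k2) and G3 (inert).  Primary degradation
    pathways are limited by their oxidant through Monod terms and
    inhibited by more favourable oxidants through hyperbolic terms; the
    secondary redox reactions are bimolecular.
    """

    k1: float = 1e-3  # yr-1
    k2: float = 1e-5  # yr-1
    K_O2: float = 1e-3  # mol m-3 (= 1 uM), aerobic Monod constant
    K_NO3: float = 5e-3  # mol m-3, denitrification Monod constant
    k_O2_inhib: float = 1e-2  # mol m-3 (= 10 uM), O2 inhibition on denitrification
    K_MnO2: float = 5.0  # mol m-3 bulk, Monod constant for MnO2 reduction
    k_NO3_inhib: float = 5e-3  # mol m-3, NO3 inhibition on MnO2 reduction
    k_nit: float = 1e4  # m3 mol-1 yr-1, nitrification NH4+ + O2
    k_mnox: float = 1e3  # m3 mol-1 yr-1, Mn2+ oxidation by O2
    k_amx: float = 1e2  # m3 mol-1 yr-1, anaerobic ammonium oxidation
    D_b: float = 0.0  # m2 yr-1 biodiffusion of solids
    o2_first_order_rate: float = 0.0  # yr-1, optional lumped first-order O2 sink
    D0: dict = field(default_factory=dict)  # optional per-solute D0 override, m2 yr-1 at 0 C

    def __post_init__(self):
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "D0"
        }
        bad = [k for k, v in numeric.items() if v < 0]
        if bad:
            raise ConfigurationError(f"kinetic parameters must be >= 0: {bad}")
        if self.k1 < self.k2:
            raise ConfigurationError("k1 must be >= k2 (G1 is the more labile pool)")

    def diffusivity(self, species: str, temperature_c: float) -> float:
        """D0(T) for a solute, honouring any per-species override at 0 deg C."""
        if species in self.D0:
            a, b = _D0_COEFFS[species]
            return self.D0[species] * (1.0 + (b / a) * temperature_c)
        return molecular_diffusivity(species, temperature_c)

    def replace(self, **changes) -> "KineticParameters":
        return dataclasses.replace(self, **changes)
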