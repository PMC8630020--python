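"""Reaction network of the diagenetic model.

Primary organic-matter degradation pathways, in order of energetic
favourability: aerobic respiration (R1), heterotrophic denitrification
(R2) and MnO2 reduction (R3).  Each is limited by its terminal oxidant
through a Monod term and inhibited by the more favourable oxidants
through hyperbolic terms.  Secondary redox reactions are bimolecular:
nitrification (R4), Mn(II) oxidation by O2 (R5) and anaerobic ammonium
oxidation (R6).  For cores flagged fully oxic, R3, R5 and R6 are switched
off.

All rates are expressed per bulk sediment volume (mol m-3 bulk yr-1);
R1-R3 count carbon, R4 and R6 nitrogen, R5 manganese.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .parameters import SOLUTES, SOLIDS, KineticParameters, SiteConfig
from .units import toc_molar_to_weight_percent


class SolverStateError(ValueError):
    """Raised when the solver state handed to the rate law is invalid."""


@dataclass
class ProfileSet:
    """Depth-gridded concentrations: porewater solutes and bulk solids."""

    grid: Grid
    solutes: dict  # species -> mol m-3 porewater
    solids: dict  # pool -> mol m-3 bulk

    def __post_init__(self):
        n = self.grid.n_nodes
        for name in SOLUTES:
            if name not in self.solutes or np.asarray(self.solutes[name]).size != n:
                raise SolverStateError(f"solute {name!r} missing or wrong length")
        for name in SOLIDS:
            if name not in self.solids or np.asarray(self.solids[name]).size != n:
                raise SolverStateError(f"solid {name!r} missing or wrong length")

    def toc_molar(self) -> np.ndarray:
        """Total organic carbon, mol C m-3 bulk."""
        return self.solids["G1"] + self.solids["G2"] + self.solids["G3"]

    def toc_weight_percent(self, site: SiteConfig) -> np.ndarray:
        """Total organic carbon as percent dry weight."""
        phi = site.porosity_profile(self.grid.node_depths)
        return toc_molar_to_weight_percent(self.toc_molar(), phi, site.dry_density)


@dataclass
class RateProfiles:
    """Volumetric reaction rates along the grid, per bulk sediment volume."""

    R1: np.ndarray  # aerobic degradation, mol C m-3 yr-1
    R2: np.ndarray  # denitrification, mol C m-3 yr-1
    R3: np.ndarray  # MnO2 reduction, mol C m-3 yr-1
    R4: np.ndarray  # nitrification, mol N m-3 yr-1
    R5: np.ndarray  # Mn(II) oxidation by O2, mol Mn m-3 yr-1
    R6: np.ndarray  # anaerobic ammonium oxidation, mol N m-3 yr-1
    G1_loss: np.ndarray  # total decay of the G1 pool, mol C m-3 yr-1
    G2_loss: np.ndarray
    o2_first_order: np.ndarray  # optional lumped first-order O2 sink
    basis: dict = field(
        default_factory=lambda: {
            "R1": "mol C m-3 bulk yr-1",
            "R2": "mol C m-3 bulk yr-1",
            "R3": "mol C m-3 bulk yr-1",
            "R4": "mol N m-3 bulk yr-1",
            "R5": "mol Mn m-3 bulk yr-1",
            "R6": "mol N m-3 bulk yr-1",
        }
    )


def _monod(c, k):
    # c/(c+k) for c >= 0, continued as c/(k-c) for the marginal negative
    # excursions of a Newton iterate: C1-continuous at 0 and restoring
    return c / (np.abs(c) + k) if k > 0 else np.where(c > 0, 1.0, 0.0)


def _inhibition(c, k):
    # hyperbolic suppression by a more favourable oxidant
    return k / (k + np.abs(c)) if k > 0 else np.where(c > 0, 0.0, 1.0)


def reaction_rates(
    state: ProfileSet, p: KineticParameters, site: SiteConfig, *, _clip: bool = True
) -> RateProfiles:
    """Evaluate all volumetric reaction rates for a model state.

    During Newton iteration intermediate states may dip marginally
    negative; the sign-preserving saturation forms then act as smooth
    restoring terms, and the solver adds a stiff penalty that pins the
    converged root at non-negative values.  With ``_clip=False``
    (reporting mode) negative inputs raise instead.
    """
    c = {}
    for name in SOLUTES:
        arr = np.asarray(state.solutes[name], dtype=float)
        if not _clip and np.any(arr < 0):
            raise SolverStateError(f"negative concentration in {name}")
        c[name] = arr
    g1 = np.asarray(state.solids["G1"], dtype=float)
    g2 = np.asarray(state.solids["G2"], dtype=float)
    mno2 = np.asarray(state.solids["MnO2"], dtype=float)

    phi = site.porosity_profile(state.grid.node_depths)
    pot = p.k1 * g1 + p.k2 * g2  # potential C oxidation, mol C m-3 bulk yr-1

    f_o2 = _monod(c["O2"], p.K_O2)
    f_no3 = _monod(c["NO3"], p.K_NO3) * _inhibition(c["O2"], p.k_O2_inhib)
    f_mno2 = (
        _monod(mno2, p.K_MnO2)
        * _inhibition(c["O2"], p.k_O2_inhib)
        * _inhibition(c["NO3"], p.k_NO3_inhib)
    )

    r1 = pot * f_o2
    r2 = pot * f_no3
    # bimolecular rates act on porewater concentrations; the phi factor
    # converts them to the bulk basis shared by all rates
    r4 = p.k_nit * c["NH4"] * c["O2"] * phi
    if site.fully_oxic:
        zero = np.zeros_like(r1)
        r3, r5, r6 = zero, zero.copy(), zero.copy()
    else:
        r3 = pot * f_mno2
        r5 = p.k_mnox * c["Mn"] * c["O2"] * phi
        r6 = p.k_amx * c["NH4"] * c["NO3"] * phi

    limit_sum = f_o2 + f_no3 + (0.0 if site.fully_oxic else f_mno2)
    return RateProfiles(
        R1=r1,
        R2=r2,
        R3=r3,
        R4=r4,
        R5=r5,
        R6=r6,
        G1_loss=p.k1 * g1 * limit_sum,
        G2_loss=p.k2 * g2 * limit_sum,
        o2_first_order=p.o2_first_order_rate * phi * c["O2"],
    )


# Stoichiometric couplings (mol per mol of the rate's own basis):
#   O2  sink:  R1 + 2 R4 + 0.5 R5          (aerobic C, nitrification, Mn oxidation)
#   NO3 source R4; sinks 0.8 R2 + R6        (denitrification to N2; anammox)
#   NH4 source (R1+R2+R3)/rCN; sinks R4+R6  (N mineralisation; oxidation)
#   DIC source R1 + R2 + R3
#   Mn  source 2 R3; sink R5
#   MnO2 sink 2 R3; source R5
def source_terms(rates: RateProfiles, site: SiteConfig) -> dict:
    """Net volumetric source of every state variable, mol m-3 bulk yr-1."""
    r = rates
    n_min = (r.R1 + r.R2 + r.R3) / site.cn_ratio
    return {
        "O2": -(r.R1 + 2.0 * r.R4 + 0.5 * r.R5 + r.o2_first_order),
        "NO3": r.R4 - 0.8 * r.R2 - r.R6,
        "NH4": n_min - r.R4 - r.R6,
        "Mn": 2.0 * r.R3 - r.R5,
        "DIC": r.R1 + r.R2 + r.R3,
        "G1": -r.G1_loss,
        "G2": -r.G2_loss,
        "G3": np.zeros_like(r.R1),
        "MnO2": r.R5 - 2.0 * r.R3,
    }
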