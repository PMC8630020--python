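# Standard-state thermodynamic properties at 25 C, 1 bar, for the aqueous
# nitrification reaction system.  dGf/dHf: standard Gibbs energy/enthalpy of
# formation (kJ mol-1) from standard compilations of aqueous species
# properties (CODATA-consistent values as tabulated in common geochemistry
# references); ion_size_A: extended Debye-Huckel ion-size parameter (Angstrom,
# Kielland convention); volume_cm3_mol: standard partial molal volume.
# H+ values are zero by the conventional standard state.
species,dGf_kJ_mol,dHf_kJ_mol,charge,ion_size_A,volume_cm3_mol
NH3,-26.57,-80.29,0,0.0,24.4
NH4+,-79.31,-132.51,1,2.5,18.1
O2,16.54,-11.70,0,0.0,32.0
NO3-,-108.74,-205.00,-1,3.0,29.0
H2O,-237.18,-285.83,0,0.0,18.07
H+,0.0,0.0,1,9.0,0.0
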