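"""Gibbs energy and power supply of nitrification down a sediment core.

The in situ energy yield per electron is nearly constant with depth, so the
orders-of-magnitude decline in power supply tracks the nitrification rate.
"""

import numpy as np

import sedpower as sp

tr = sp.make_scenario("AMOR-like")
thermo = sp.gibbs_energy_profile(tr.profiles, tr.site)  # 8-electron convention
power = sp.power_supply_profile(thermo, tr.rates)

oxic = thermo.oxic_mask
dg = thermo.dg_per_e[oxic]
ps = power.ps[oxic & (power.ps > 0)]
print(f"standard-state dG0(T,P): {thermo.dg0:.1f} kJ per mol reaction")
print(f"in situ dG: {dg.min():.1f} .. {dg.max():.1f} kJ (mol e-)-1 "
      f"({2*dg.min():.1f} .. {2*dg.max():.1f} in the 4-equivalent convention)")
print(f"power supply: {ps.min():.2e} .. {ps.max():.2e} W m-3")
# dG varies by a few kJ while the power supply spans ~3 orders of magnitude
# within this core: the rate, not the thermodynamics, sets the power.
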