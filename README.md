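# sedpower

Steady-state diagenetic modelling and nitrification bioenergetics of marine
oxic sediments — from porewater chemistry to the power available per
ammonia-oxidizing cell.

## The problem

Most microbes below the seafloor live at extreme energy limitation, and a
central question in deep-biosphere ecology is how much power a single cell
needs to stay alive. Ammonia-oxidizing archaea (AOA, family
Nitrosopumilaceae) are an ideal study group: their catabolism is a single
well-defined reaction (aerobic ammonia oxidation), they carry a clean
molecular marker (*amoA*), and their substrate turnover leaves a clear
geochemical imprint (O₂ consumption, NO₃⁻ accumulation). `sedpower`
implements the quantitative chain that turns sediment geochemistry and
community data into a cell-specific power estimate:

1. **Reaction–transport model.** A 1-D steady-state finite-volume model of
   the oxic sediment column with three organic-matter pools (3-G kinetics,
   reactivities k₁ > k₂, third pool inert), the primary degradation
   pathways — aerobic respiration (R₁), denitrification (R₂), MnO₂
   reduction (R₃) with Monod limitation and hyperbolic inhibition — and the
   bimolecular secondary reactions nitrification (R₄ = k_nit·[NH₄⁺]·[O₂]),
   Mn²⁺ oxidation (R₅) and anammox (R₆). Solutes (O₂, NO₃⁻, NH₄⁺, Mn²⁺,
   DIC) carry tortuosity-corrected diffusion (θ² = 1 − 2 ln φ) and burial
   advection; solids (G₁, G₂, G₃, MnO₂) carry burial with prescribed
   deposition fluxes. The solver is a damped Newton iteration with
   pseudo-transient continuation.
2. **Nitrification energetics.** ΔG_r = ΔG_r⁰(T, P) + RT ln Q_r for
   NH₃ + 2 O₂ → NO₃⁻ + H⁺ + H₂O, with NH₃ from the pH-dependent
   NH₃/NH₄⁺ equilibrium ([NH₃] = [NH₄⁺]·10^(pH−pKa), pKa = 9.3), activities
   from an extended Debye–Hückel model at seawater ionic strength, and the
   power supply P_s = |ΔG_r|·R₄ in W m⁻³, computed inside the oxic zone
   (O₂ ≥ 1 µM).
3. **AOA abundance.** The AOA fraction of the community declines with
   relative depth x = z/OPD in the oxic zone as y = a·e^{bx}; the fitted
   curve (with confidence band) times total cell numbers gives absolute
   AOA abundance, cross-checkable against *amoA* qPCR.
4. **Cell-specific power.** P_cell = P_s·10⁻⁶/[AOA cells cm⁻³], in
   W cell⁻¹, compared against laboratory cultures
   (0.1–1 fmol N cell⁻¹ h⁻¹ at 50–80 kJ (mol e⁻)⁻¹).

Because no field dataset ships with the package, a synthetic-site module
provides five presets spanning >3 orders of magnitude in organic flux and
oxygen penetration — from a productive Arabian-Sea-type core (OPD ~0.15 m)
to a South-Pacific-Gyre-type column that stays oxic to 67 m — plus noisy
observation generators with retained ground truth, so every stage of the
pipeline is testable end to end.

## Worked example

```python
import sedpower as sp

cfg = sp.RunConfig.from_dict({"preset": "AMOR-like", "seed": 7})
bundle = sp.run_pipeline(cfg)
```

or at the library level (`examples/` has one script per capability):

```text
$ python examples/simulate_preset.py
site: SAST-like  (F_org = 0.24 mol C m-2 yr-1)
oxygen penetration depth: 0.161 m
nitrification rate range: 2.54e-08 .. 4.25e-01 mol N m-3 yr-1
peak nitrate: 36.5 uM
worst element budget closure: 2.88e-13

$ python examples/nitrification_energetics.py
standard-state dG0(T,P): -356.4 kJ per mol reaction
in situ dG: -42.1 .. -38.5 kJ (mol e-)-1 (-84.3 .. -77.1 in the 4-equivalent convention)
power supply: 7.56e-08 .. 2.73e-04 W m-3

$ python examples/cell_power_pipeline.py
oxic-zone cell-specific power: 1.1e-18 .. 5.2e-18 W cell-1
geometric mean: 3.0e-18 W cell-1
laboratory culture range: 5.6e-15 .. 8.9e-14 W cell-1
gap to culture conditions: ~3.3 orders of magnitude
```

Reading the numbers: the oxygen penetration depth marks the oxic–anoxic
boundary the energetics are confined to; the in situ Gibbs energy varies by
only a few kJ per electron down-core while the power supply spans orders of
magnitude, so the *rate* controls the power; and the per-cell power of
~10⁻¹⁸ W sits three-plus orders of magnitude below any cultured ammonia
oxidizer — the basal-power regime of the deep biosphere.

`examples/aoa_regression.py` and `examples/calibrate_synthetic.py` show the
abundance regression with its 95% band and the recovery of {k₁, F_org,
k_nit} from noisy profiles.

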