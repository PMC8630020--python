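# Methods

This note documents the model equations, the numerical choices, the
synthetic-data design, and the limits of what the shipped tests can show.

## Reaction–transport model

**State.** Five porewater solutes (O₂, NO₃⁻, NH₄⁺, Mn²⁺, DIC; mol m⁻³ of
porewater) and four solids (organic pools G₁, G₂, G₃ and MnO₂; mol m⁻³ of
bulk sediment) on a 1-D vertical domain, z = 0 at the sediment–water
interface, positive down.

**Transport.** Solutes: molecular diffusion with the tortuosity correction
θ² = 1 − 2 ln φ, porosity φ(z) = φ∞ + (φ₀ − φ∞)e^(−βz) (defaults φ₀ = 0.85,
φ∞ = 0.75, β = 1 m⁻¹), interface diffusivities by harmonic mean, and burial
advection at the sedimentation rate w. Free-solution diffusivities use
linear temperature fits (e.g. D₀(O₂) = (11.70 + 0.344 T[°C])·10⁻⁶ cm² s⁻¹).
Solids: upwind burial advection (optional biodiffusion constant, default
0). Compaction-driven velocity divergence is neglected: w is constant.

**Reactions.** With pot = k₁G₁ + k₂G₂ the potential carbon oxidation rate:

- R₁ = pot · O₂/(O₂+K_O₂)
- R₂ = pot · NO₃/(NO₃+K_NO₃) · k_inh/(k_inh+O₂)
- R₃ = pot · MnO₂/(MnO₂+K_MnO₂) · inhibition by both O₂ and NO₃⁻
- R₄ = k_nit [NH₄⁺][O₂] φ, R₅ = k_mnox [Mn²⁺][O₂] φ, R₆ = k_amx [NH₄⁺][NO₃⁻] φ

(the φ factor converts porewater-based bimolecular rates to the common
bulk basis). Stoichiometric couplings: O₂ sink R₁ + 2R₄ + 0.5R₅; NO₃⁻
source R₄, sinks 0.8R₂ + R₆; NH₄⁺ source (R₁+R₂+R₃)/rCN, sinks R₄ + R₆;
DIC source R₁+R₂+R₃; Mn²⁺ source 2R₃, sink R₅. Anammox is written on
NO₃⁻ with 1:1 N consumption because no nitrite state is carried; this is
the minimal bimolecular closure of the N budget. For cores flagged fully
oxic, R₃/R₅/R₆ are disabled. rCN defaults to Redfield (106/16).

**Boundary conditions.** Fixed solute concentrations at z = 0 (NH₄⁺
default 0.01 µM — note this produces a thin artificial nitrification spike
at the surface of oligotrophic presets, discussed below); prescribed solid
deposition fluxes F_org·f_i (and an MnO₂ flux); zero diffusive gradient
plus advective burial export at the base.

**Solver.** Vertex-centred finite volumes (nodes on interfaces including
z = 0 and L; half-cells at the boundaries), optionally geometrically
refined toward the surface. The nonlinear system is solved by damped
Newton with a colored finite-difference Jacobian (a 3-node × 9-variable
coloring needs 27 residual evaluations per Jacobian) and sparse LU.
When cold-start Newton stalls, pseudo-transient continuation (implicit
Euler, step adapted to the remaining residual) carries the state into the
Newton basin. Two details matter for robustness:

- Saturation/inhibition terms are continued sign-preservingly for
  marginally negative iterates (c/(|c|+K)), which keeps the Jacobian
  C1-continuous at zero.
- A stiff penalty −λ·min(c, 0) removes the spurious steady roots with
  small negative tails that otherwise exist below oxidant depletion,
  pinning the converged solution at non-negative values (residual-level
  negatives are below 10⁻¹¹ of each variable's scale).

Convergence is declared at a scaled residual below 1e−8 (per-species
denominators from the cold-start residual floored by a characteristic
transport rate). The 1e−8 default reflects the round-off floor of
finite-difference Jacobians on fine grids; element budgets still close to
~1e−8–1e−13, five orders inside the 1e−3 audit threshold. The discrete
scheme is second order: against the closed form C_B cosh(α(L−z))/cosh(αL)
for a first-order O₂ sink the measured L∞ errors are 3.4e−6 (200 nodes)
and 3.3e−8 (2000 nodes), order ≈ 2.0.

**Diagnostics.** Oxygen penetration depth (OPD) is the first depth where
O₂ < 1 µM, linearly interpolated. RMSE between model and data is the root
*mean* square misfit per species (the mean form is used even where field
conventions are ambiguous between sum and mean; with a fixed dataset the
two differ by a constant factor √n and rank models identically).
The NO₃⁻/−O₂ slope over a depth window estimates the C/N ratio of
degrading organic matter; in a transport-reaction steady state the
expected slope is ≈ 1/(rCN + 2) (N released per C over O₂ demand per C
including nitrification), modulated by the NO₃⁻/O₂ diffusivity ratio
(~0.85), which is why the forward-model slope (0.103) sits ~11% below the
pure stoichiometric value 0.116.

**Calibration.** The original workflow this formalises was visual curve
matching; here it is weighted least squares: residuals (model − data)
normalised per species by the maximum measured value, free parameters
(kinetic constants and/or F_org) optimised in log space with
`scipy.optimize.least_squares` (TRF, bounded), warm-starting each solve
from the previous profile. Identifiability is data-limited, not
solver-limited: with the 0.1 µM detection limit applied, oxic-zone NH₄⁺
(~10⁻³ µM) is entirely censored and k_nit is unidentifiable, and at
gyre-type sites k₁'s signal lives in the top decimetres. The recovery
tests therefore sample depths stratified on the refined grid's node index
(dense near the surface, as real porewater sampling is) and disable the
detection limit; under those conditions {k₁, F_org, k_nit} come back
within a few percent at 10% noise on the AMOR-like, NP-like and SAST-like
presets. SPG/NPG-like presets leave k₁ and k_nit weakly constrained — a
faithful reflection of how little information near-inert profiles carry.

## Nitrification energetics

Reaction: NH₃ + 2 O₂(aq) → NO₃⁻ + H⁺ + H₂O, n_e = 8 electrons. NH₃ from
[NH₄⁺]·10^(pH−pKa), pKa 9.3. ΔG_r⁰ at in situ T and P by van 't Hoff
(constant reaction enthalpy from 25 °C formation values) plus a constant
reaction-volume term ΔV(P − 1 bar), ΔV ≈ −41 cm³ mol⁻¹; hydrostatic
pressure 1 bar + depth/10 m. This captures the dominant corrections at
the few-kJ level; a full revised-HKF equation of state is deliberately
out of scope, and the tests pin the formula (reference-state sums,
closed-form sensitivities RT·ν/n_e) rather than absolute ΔG targets.
Activities: molality ≈ concentration/1000, extended Debye–Hückel
log₁₀γ = −A z²√I/(1 + B å √I) with A, B linear in T (A: 0.4918→0.5092,
B: 0.3248→0.3283 over 0–25 °C), default ionic strength 0.7 mol kg⁻¹,
a(H₂O) = 1, a(H⁺) = 10^(−pH). Calculations are masked outside the oxic
zone and where a substrate activity is non-positive.

Per-electron energies divide by 8 by default. A 4-electron-equivalent
mode is provided because the published laboratory per-cell power range
(5.6×10⁻¹⁵–8.8×10⁻¹⁴ W cell⁻¹ from 0.1–1 fmol N cell⁻¹ h⁻¹ at 50–80 kJ
(mol e⁻)⁻¹) is only internally consistent under that convention; the
volumetric power supply P_s = |ΔG_per_e|·n_e·R₄ is independent of the
choice. `lab_reference_power` defaults to the 4-equivalent mode for
exactly this comparability reason, and both conventions can be reported
side by side via the pipeline's `electron_equivalents` option.

## AOA regression and cell power

The fraction of AOA in the community declines as y = a·e^{bx} with
relative depth x = z/OPD. The default fit minimises untransformed
residuals (matching the common curve-fitting-tool workflow), with
starting values a = max(y), b = −1 and bounds a ∈ (0, 100], b ∈ [−10, 0]
(the upper b bound is relaxed to +10 so degenerate flat data converge to
b = 0). Because the generator's fraction scatter is multiplicative, the
residuals are strongly heteroscedastic; the default fit's parameter
covariance is therefore computed with a heteroscedasticity-robust (HC1)
sandwich estimator, and confidence bands use the delta method with a
t-quantile (df = n − 2). Note the untransformed fit estimates the
conditional *mean* curve a·e^{bx}·e^{σ²/2} (13% above the noiseless curve
at σ = 0.5), so its band is not expected to cover the noiseless curve at
nominal rate near the design centre. The `log_space=True` mode fits
ln y by OLS, estimates the median curve unbiasedly, and is the mode under
which the 95% band empirically covers the true curve in 94–96% of 200
simulations at n = 40; the interval-calibration audit runs in that mode.

Predictions are refused for x > 1: at the oxic–anoxic transition AOA
abundances are elevated and the regression does not extrapolate.
Absolute abundance is totals × fraction/100 with the CI propagated
multiplicatively; the qPCR cross-check reports per-depth fold differences
max(est, q)/min(est, q). Cell-specific power P_cell = P_s·10⁻⁶/abundance
(W cell⁻¹), with the abundance CI propagated through the reciprocal.

## Synthetic sites

Five presets emulate the studied regimes, with water depths and
sedimentation rates from the published site table and boundary
concentrations at typical bottom-water values:

| preset | F_org (mol C m⁻² yr⁻¹) | domain | OPD | notes |
|---|---|---|---|---|
| SAST-like | 0.24 | 0.4 m | ~0.16 m | denitrification active |
| AMOR-like | 0.012 | 10 m | ~6.2 m | ridge flank (GC08 metadata) |
| NP-like | 1.2e−3 | 30 m | > 30 m | fully oxic |
| NPG-like | 5e−4 | 20 m | > 20 m | fully oxic |
| SPG-like | 1.4e−4 | 67 m | > 67 m | fully oxic |

Reactivities (k₁ 1e−5–4e−4 yr⁻¹, k₂ = k₁/100–k₁/30) were chosen once per
preset so each regime reproduces its oxygen-penetration scale; they are
presets, not reproductions of any site's calibrated values. All presets
ship with `mno2_flux = 0`: with a surface MnO₂ flux the oxic-front Mn
redox loop has near-unit recycle gain and its steady state carries an
implausibly large MnO₂ peak approached over ~10⁵ yr (verified by time
integration), a regime outside what these presets are meant to represent.
The Mn pathway itself (R₃/R₅, stoichiometry, budget) remains implemented
and unit-tested.

Observation generators: geochemical profiles get multiplicative lognormal
noise (σ = √ln(1+cv²)) at depths stratified on the grid's node index, with
NO₃⁻/NH₄⁺ below 0.1 µM stored as left-censored records (configurable);
community truth is a = 22.3%, b = −2 with lognormal scatter σ = 0.5,
total cells N(z) = N₀·(max(z, 1 cm)/1 cm)^(−0.7) with N₀ from 3×10⁸
(SAST-like) down to 5×10⁵ cells cm⁻³ (SPG-like), and qPCR copies carry
10^N(0, 0.3²) scatter. All draws come from one seeded
`numpy.random.default_rng`; identical seeds reproduce bit-identically.

What the synthetic data do *not* emulate: nitrite dynamics, core-top
coring disturbance, spatial heterogeneity or anoxic-zone N cycling beyond
the minimal anammox closure — so passing recovery tests demonstrate the
pipeline's internal consistency, not field accuracy.

The fixed 0.01 µM NH₄⁺ top boundary produces a thin (~mm) nitrification
spike at the surface of the oligotrophic presets, where the depth-integrated
R₄ is dominated by boundary-fed ammonium rather than mineralisation. The
supply-limitation check (integrated R₄ invariant under k_nit × 0.1–10)
therefore runs with NH₄⁺(0) = 0, and end-to-end per-cell-power range checks
exclude the top 10 cm, where population size is in any case controlled by
processes outside the model.

## Problem sizes and runtime

Default grids use 150 nodes with a 1.04 per-cell geometric refinement
toward the surface (the closed-form oracle uses uniform 200- and
2000-node grids). A preset solve takes well under a second; the full test
suite runs in ~15 s and `scripts/acceptance.py` in ~10 s on one CPU.

## Known limitations

- No transient mode, bioturbation/bioirrigation (beyond a biodiffusion
  constant), S/Fe/CH₄ cycling, isotopes, or nitrite state variable.
- Thermodynamics approximate CHNOSZ-grade equations of state by van 't
  Hoff + constant ΔV; errors grow beyond a few kJ only far outside the
  0–25 °C, 0–600 bar envelope used here.
- Carbonate speciation is not modelled; DIC diffuses with the bicarbonate
  coefficient.
- The strong-Mn-recycling regime converges poorly and is excluded from
  presets (above).
- Calibration identifiability depends on uncensored NH₄⁺ data; with a
  realistic 0.1 µM detection limit k_nit is unconstrained.
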