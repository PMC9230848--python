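# Methods

This note records the models implemented in `asdsorption`, the assumptions
behind them, the numerical choices, and the places where the published
description of these methods is ambiguous and a decision had to be made.

## Thermodynamic model

### PC-SAFT

The residual Helmholtz energy per molecule, reduced by kT, is the
perturbed-chain SAFT sum a_res = a_hc + a_disp + a_assoc:

- **Hard chain**: Boublik–Mansoori hard-sphere mixture term with
  temperature-dependent segment diameters d_i = σ_i(1 − 0.12 e^(−3u_i/kT)),
  plus the chain-connectivity correction −Σ x_i(m_i − 1) ln g_ii at the
  hard-sphere contact value.
- **Dispersion**: second-order perturbation with the standard universal
  constants; Berthelot–Lorentz combining, u_ij = √(u_i u_j)(1 − k_ij(T)),
  σ_ij = (σ_i + σ_j)/2.
- **Association**: donor/acceptor site types with integer multiplicities per
  molecule (water 1/1, IND 3/3, PVP 231/231, PVPVA 653/653). Association
  strength Δ_ij = σ_ij³ g_ij κ_ij (e^(ε_ij/kT) − 1); cross parameters by
  Wolbach–Sandler, ε_ij = (ε_i + ε_j)/2 and
  κ_ij = √(κ_i κ_j)·(√(σ_iσ_j)/σ_ij)³. The polymers carry zero
  self-association energy but real site counts, so they associate *only*
  with water (induced association) — a pure polymer contributes nothing to
  a_assoc because e^0 − 1 = 0.

Site fractions solve the coupled mass-action equations by damped successive
substitution (damping 0.5) with a Newton finisher once the update falls
below 1e-2; tolerance 1e-12 on the update, 500-iteration cap, warm-started
between calls. Because the Helmholtz energy is stationary in the site
fractions at the solution (the Q-function property), density and
composition derivatives are taken at *fixed* site fractions; all first
derivatives of a_res are therefore fully analytic and are verified against
central finite differences in the test suite.

Polymers are monodisperse pseudo-components at their published molar
masses. Their mole fractions in wet films are O(1e-6); compositions are
handled as ratios of positive terms throughout, never differences, so the
solvers are stable down to that range.

Internal units: K, molecules/Å³, energies over kB; pressures cross the
interface in Pa. The compressibility factor is Z = 1 + ρ̃ ∂a_res/∂ρ̃ and
component fugacities (Pa) follow from

    ln f_i = a_res + ∂a_res/∂x_i − Σ_j x_j ∂a_res/∂x_j + (Z − 1) + ln(ρ̃ x_i kB T)

with unconstrained composition derivatives at fixed T and ρ̃. A component at
x_i = 0 reports ln f_i = −∞ rather than raising.

### Solvers

- **Density**: p(ρ̃) = p target, bracketed on a log grid of packing
  fractions in (1e-12, 0.74) and refined with Brent's method to ~1e-15
  relative in ρ̃. A "liquid" hint walks down from close packing, "vapor"
  walks up from the ideal-gas end; with no hint every root is found and the
  lowest-Gibbs-energy one returned.
- **Saturation**: pure-component vapor–liquid coexistence by successive
  substitution on the fugacity imbalance, p ← p·exp(ln f_L − ln f_V),
  converged to |Δln f| < 1e-12 and verified below 1e-10. With the packaged
  water set this gives p_sat(298.15 K) = 3.151 kPa and a liquid density of
  996.9 kg/m³ — both within 1 % of the experimental values.

### NET-GP (glassy films)

A glassy film is below its glass transition: its volume is not the
equilibrium volume but an internal state variable. The pseudo-equilibrium
water fugacity is the chemical potential evaluated at the *imposed* number
density fixed by the swelling relation

    v_NE = v0_NE (1 − w_w) / (1 − k_w^NE · RH²)

(no pressure match is attempted; Z enters the fugacity expression at the
imposed density). The dry-film inputs mix over the two dry components as

    v0_NE = w0a·v0a_NE + w0p·v0p_NE
    k_w^NE = w0a·(v0a_NE/v0_NE)·k_wa^NE + w0p·(v0p_NE/v0_NE)·k_wp^NE

The API's glassy specific volume is taken equal to its PC-SAFT equilibrium
value at 298.15 K and 1 bar (computed once and cached), and the API–water
swelling coefficient is zero, both per the published parameterization.

**Branch rule.** At every RH both descriptions are solved; the equilibrium
branch wins iff its water *mole* fraction exceeds the glassy one (ties go
to the glassy branch). Both solutions cross continuously at the switch, so
the isotherm has no jump there.

**Ambiguity — the RH exponent.** The published rendering of the swelling
relation ("1 − kwNE RH2") does not typeset the exponent. The quadratic
reading is implemented as the default and the exponent is a configurable
parameter of `SorptionSystem`. The quadratic form reproduces the measured
mid- and high-RH endpoints of all four ASD systems well (most within a few
tenths of a wt%), while the linear form overshoots them badly; the price of
the quadratic form is a systematic underprediction of the small first-step
uptakes below ~0.3 RH, which should be kept in mind when using predictions
in that corner.

### Isotherm solver

p equals the water partial pressure p_w = p_sat·RH (polymer and API are
involatile); the vapor-phase water fugacity is the PC-SAFT vapor root at
(T, p_w) by default, with an ideal-gas option for sensitivity checks. The
isofugacity residual ln f_w^L(w_w) − ln f_w^V is monotone in w_w; it is
bracketed by a 16-point log-spaced scan of w_w in (1e-8, 0.95) — which
survives the extremely flat low-RH region — and Brent-refined essentially
to machine precision (residual ≪ 1e-10). States pushed beyond close
packing by the imposed glassy volume read as a huge positive residual,
consistent with monotonicity.

The glassy-limit humidity RH* solves Tg(w_w(RH)) = T by a coarse scan
(step 0.05) plus bisection to 1e-4 in RH, with the wet Tg from the
Gordon–Taylor equation below.

## Glass-transition machinery

Gordon–Taylor with the water constant fixed at 1:

    Tg = (K_a w_a Tg0_a + K_p w_p Tg0_p + w_w Tg0_w) / (K_a w_a + K_p w_p + w_w)

The packaged constants are the published ones (PVP 0.253, PVPVA 0.3,
IND 0.11). The Simha–Boyer rule K = (ρ_w Tg_w)/(ρ_i Tg_i) reproduces the
PVPVA value (0.297 ≈ 0.3) but gives 0.246 for PVP where 0.253 is printed;
the printed value is packaged and the discrepancy is asserted in a test.

The plasticization factor Ψ_w = (Tg,dry − Tg,wet)/(Tg,dry − T) is 0 for the
dry glass and 1 when water has pulled the glass transition down to the
system temperature. It is undefined (raises) for a system already rubbery
when dry.

## Kinetics

The plane-sheet series is used with 20 terms when fitting or predicting.
As printed, the series' index expression cannot satisfy the initial
condition (it reads "(2+q)" and a sign-less exponent without π²); the
standard plane-sheet solution with (2q+1)², prefactor 8/((2q+1)²π²) and
exponent −(2q+1)²π²·D_w t/(4L0²) is implemented — a typography correction,
isolated in one function. Note the 20-term truncation leaves ~1 % of the
step amplitude at t = 0 (the tail of Σ 8/((2q+1)²π²) decays like 2/(π²q));
the synthetic generator therefore uses 200 terms so that emulated data are
converged to 0.1 %.

Per sorption step, all water-concentration-dependent quantities are frozen
at the intermediate composition w_w,eval = 0.3·w_w0 + 0.7·w_w∞ (the Vrentas
rule), giving

- Γ_w″ = ∂ln f_w/∂ln w_w by central difference (relative step 1e-4) on the
  branch the isotherm selected, with the glassy volume evaluated at the
  step's target RH. Step-halving stability of the difference is tested.
- ω0² = (L0/L)² from volume-additive swelling with the water density
  997 kg/m³ and a mass-weighted dry-film density. The printed form
  "(L L0)2" with the surrounding text calling it a *flux reduction* is
  read as the ratio ≤ 1; the reciprocal is available as a switch.
- Ð_wa″, Ð_wp″ by piecewise-linear interpolation of the packaged
  diffusivity tables in Ψ_w, **clamped** (with a warning) outside the node
  range — the plasticization factor exists precisely to avoid
  extrapolation, so none is ever performed.
- Ð_w″ from mass-weighted friction additivity. The printed mixing formula
  inverts a weighted sum of diffusivities, which is dimensionally
  inconsistent; the harmonic-mean (friction-additive) form is implemented,
  consistent with the observation that the ASD's segmental diffusivity lies
  between the two pure-substance values at every composition.

Molecular→segmental conversion for the API table uses
Ð″ = Ð·(1 − x_w)/(1 − w_w).

**Fitting.** `fit_fickian_d` fits log10 D_w (initial guess from the
half-time, D t_1/2/L0² ≈ 0.196) together with the step asymptote as a
dimensionless multiple of the trace amplitude, so that steps truncated by
the termination criterion do not bias the diffusivity. Asymptotic
confidence intervals come from the Gauss–Newton covariance; a
sign-flipping early/late residual pattern flags sigmoidal (anomalous,
relaxation-controlled) sorption, which a single Fickian constant cannot
reproduce — the model's known limitation near the glass transition.

## Synthetic experiments

The generator emulates a gravimetric RH-step experiment: a flat drying
stub at RH 1e-5 (from which readers recover the dry mass as the mean of
the last 10 plateau points), then one Crank transient per scheduled RH with
endpoints from an explicit list, sampled every 60 s and terminated when the
smoothed mass-change rate (linear fit over a 5-sample window) drops below
1e-4 wt%/min, capped at D t/L0² = 12. Noise is independent Gaussian,
scaled to the step amplitude (σ = 0.01 mimics a sub-microgram balance on
~10 µg amplitudes), and a seed is mandatory whenever σ > 0. What the
generator does *not* emulate: anomalous/sigmoidal step shapes, RH-control
transients, buoyancy and surface adsorption — so kinetics tests passing on
synthetic data demonstrate solver/fitter closure, not the Fickian model's
adequacy for real near-Tg steps.

## Parameters

`asdsorption/data/parameters.yaml` mirrors the published parameter tables
column for column (PC-SAFT pure components, binary k_ij, NET-GP volumes and
swelling coefficients, Gordon–Taylor inputs, diffusivity tables, the
six-step RH schedule and film geometry), each entry with a provenance
string; the loader validates every invariant and rejects unknown keys, and
a registry round-trips through YAML identically.

One printed value is impossible as written: the PVP–IND interaction
parameter "k_ij = −0.0118 T + 0.0922" evaluates to ≈ −3.4 at 298 K, outside
the admissible (−1, 1). The slope is read as −1.18e-4 K⁻¹ (a scale slip),
giving k_ij(298.15 K) = 0.0570; the value lives in the data file, not in
code, and the interpretation is logged at load time.

## Problem sizes and runtimes

The shipped analyses are desk-scale by construction: isotherms on
~20–30-point RH grids, glassy-limit searches needing ~25 isofugacity solves
each, kinetics closure on 50 synthetic steps, and a Crank-vs-PDE
cross-check on a 300-node Crank–Nicolson grid. The full test suite runs in
about a minute; the acceptance script in well under one.

## Known limitations

- Anomalous (relaxation-controlled) sorption steps are fitted only in the
  time-constant sense; their sigmoidal shape is flagged, not modelled.
- Low-RH (< ~0.3) uptake of glassy films is systematically underpredicted
  by a few tenths of a wt% up to ~1.5 wt% depending on the system (see the
  RH-exponent discussion above).
- Polymers are monodisperse pseudo-components; no polydispersity, no
  ternary residual-solvent effects, no desorption hysteresis.
- Gordon–Taylor and the plasticization factor assume a single, miscible
  amorphous phase throughout.
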