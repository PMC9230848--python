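# asdsorption

Predictive water sorption in amorphous solid dispersions (ASDs): equilibrium
and pseudo-equilibrium **water-sorption isotherms** from the PC-SAFT equation
of state combined with the Non-Equilibrium Thermodynamics of Glassy Polymers
(NET-GP), and **water-sorption kinetics** from Crank plane-sheet diffusion
driven by segmental Maxwell–Stefan diffusivities.

## Who this is for

Formulation scientists and physical pharmacists who need to know how much
water an amorphous drug–polymer film takes up at a given relative humidity,
and how fast — *before* running a dynamic vapor sorption (DVS) experiment.
The package ships the published pure-component and binary parameters for
PVP K25, PVPVA64, amorphous indomethacin (IND) and water, so complete
RH-step experiments on these systems are predicted with no sorption data
about the mixed system at all.

## The model

**Isotherms.** Water uptake at relative humidity RH follows the isofugacity
criterion

    f_w^L(T, p, V, x) = f_w^V(T, p_w),     p_w = p_sat(T) · RH

with the condensed-phase fugacity from PC-SAFT
(a_res = a_hc + a_disp + a_assoc, Berthelot–Lorentz mixing with binary k_ij,
Wolbach–Sandler cross association). A rubbery film is evaluated at its
equilibrium volume V_EQ; a glassy film is in *pseudo*-equilibrium at a
non-equilibrium volume imposed by the swelling relation

    (v0_NE / v_NE)(1 − w_w) = 1 − k_w^NE · RH²

whose dry-film parameters mix over polymer and API by mass (specific volume)
and by volume (swelling coefficient). The equilibrium description takes over
exactly when it predicts more water than the glassy one (x_w^EQ > x_w^NE).

**Kinetics.** Each RH step is a plane-sheet sorption transient

    m_w(t) = m_w0 + (m_w∞ − m_w0)·[1 − Σ_q 8/((2q+1)²π²) · e^(−(2q+1)²π² D_w t / 4L0²)]

with the apparent Fickian diffusivity factorized as
D_w = ω0² · Γ_w″ · Ð_w″: a film-swelling frame correction ω0² = (L0/L)², the
thermodynamic factor Γ_w″ = ∂ln f_w/∂ln w_w, and the segmental
Maxwell–Stefan diffusivity Ð_w″ mixed from the neat polymer and neat API
values by mass-weighted friction additivity,
1/Ð_w″ = w0a/Ð_wa″ + w0p/Ð_wp″. Both pure-substance diffusivities are
tabulated against the **plasticization factor**

    Ψ_w = (Tg,dry − Tg,wet) / (Tg,dry − T),    Tg from the Gordon–Taylor equation,

the free-volume coordinate on which the water-concentration dependencies of
polymer, API and ASD collapse — so the ASD diffusivity needs interpolation
only, never extrapolation.

## Worked example

```python
from asdsorption.registry import load_registry
from asdsorption.netgp import DryASDSpec
from asdsorption.isotherm import SorptionSystem, solve_water_uptake, glassy_limit_rh

registry = load_registry()
asd = SorptionSystem(registry, DryASDSpec(polymer="pvpva", api="ind", drug_load=0.5))

point = solve_water_uptake(asd, 298.15, 0.878)
print(f"ww = {100 * point.ww:.2f} wt% ({point.branch} branch, Tg = {point.tg:.1f} K)")
print(f"glassy up to RH = {glassy_limit_rh(asd, 298.15):.3f}")
```

prints

```
ww = 7.78 wt% (NE branch, Tg = 299.0 K)
glassy up to RH = 0.884
```

— at 87.8 % RH the 50 % drug-load PVPVA–IND film holds 7.8 % water (measured:
6.9 ± 0.2 %), still marginally glassy (its wet glass transition sits ~1 K
above 25 °C), and the film stays glassy until ~0.88 RH even though neat
PVPVA turns rubbery near 0.67 RH: indomethacin lowers the dry Tg but cuts
the water uptake far more.

The same pipeline runs from the command line:

```bash
asdsorption predict-isotherm --polymer pvpva --api ind --drug-load 0.5 --out iso.csv
asdsorption predict-experiment --polymer pvpva --api ind --drug-load 0.5 --out run
asdsorption generate-synthetic --ww-end 0.02,0.04 --d-w 2e-14,3e-14 \
    --schedule 0.2,0.4 --noise 0.01 --seed 5 --out syn.csv
asdsorption fit-kinetics --trace syn.csv --dry-density 1250 --out fits.csv
```

## DVS trace format

CSV with a header row and columns `time_s, mass_mg, target_RH, measured_RH`
(UTF-8). A trace starts with a drying segment at near-zero target RH — the
dry mass is read off that plateau — and is split into sorption steps at
every change of `target_RH`. `generate-synthetic` writes this dialect;
`fit-kinetics` reads it.

## Layout

| module | contents |
| --- | --- |
| `asdsorption.eos` | PC-SAFT with association: Helmholtz energy, analytic derivatives, fugacities, density and saturation solvers |
| `asdsorption.netgp` | glassy (non-equilibrium) volume model and pseudo-equilibrium fugacity |
| `asdsorption.isotherm` | isofugacity solver, EQ/NE branch rule, glassy-limit RH |
| `asdsorption.glass` | Gordon–Taylor, Simha–Boyer, plasticization factor |
| `asdsorption.kinetics` | Crank kinetics, Maxwell–Stefan machinery, step fitting, full-experiment prediction |
| `asdsorption.dvs` | DVS CSV I/O and the synthetic experiment generator |
| `asdsorption.registry` | validated parameter registry (packaged YAML) |
| `asdsorption.cli` | command-line workflows |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
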