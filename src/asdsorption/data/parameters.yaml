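# Parameter registry for water sorption in PVP/PVPVA-indomethacin amorphous
# solid dispersions at 298.15 K.
#
# Every entry carries a `provenance` string describing what the number is and
# where it sits in the published parameter tables for these systems.  Values
# are used as published; known typographic ambiguities are resolved in
# docs/methods.md and surfaced as explicit fields here, never silently.
#
# Units: molar_mass g/mol; segment_ratio mol/g; segment_diameter Angstrom;
# dispersion_energy, assoc_energy K (divided by kB); density kg/m^3; tg K;
# v0_ne cm^3/g; d_seg m^2/s.

components:
  water:
    molar_mass: 18.02
    segment_ratio: 0.06687
    segment_diameter: 2.7971
    dispersion_energy: 353.94
    assoc_energy: 2425.67
    assoc_volume: 0.0451
    assoc_sites: [1, 1]
    density: 997.0
    tg: 136.0
    provenance: "2B associating PC-SAFT water set; pure density and Tg from the published parameter table"
  pvp:
    molar_mass: 25700.0
    segment_ratio: 0.0407
    segment_diameter: 2.71
    dispersion_energy: 205.992
    assoc_energy: 0.0
    assoc_volume: 0.02
    assoc_sites: [231, 231]
    density: 1250.0
    tg: 441.51
    gordon_taylor_k: 0.253
    provenance: "PVP K25 PC-SAFT set (induced association, 231/231 sites); K from the Simha-Boyer rule as published"
  pvpva:
    molar_mass: 65000.0
    segment_ratio: 0.0372
    segment_diameter: 2.947
    dispersion_energy: 205.271
    assoc_energy: 0.0
    assoc_volume: 0.02
    assoc_sites: [653, 653]
    density: 1190.0
    tg: 383.9
    gordon_taylor_k: 0.3
    provenance: "PVPVA64 PC-SAFT set (induced association, 653/653 sites); K from the Simha-Boyer rule as published"
  ind:
    molar_mass: 357.79
    segment_ratio: 0.03992
    segment_diameter: 3.535
    dispersion_energy: 262.791
    assoc_energy: 886.44
    assoc_volume: 0.02
    assoc_sites: [3, 3]
    density: 1320.0
    tg: 317.6
    gordon_taylor_k: 0.11
    provenance: "amorphous indomethacin PC-SAFT set (3/3 association sites); K for IND-water from the literature"

binaries:
  - pair: [water, pvp]
    kij_intercept: -0.128
    provenance: "water-PVP dispersion correction, constant in T"
  - pair: [water, pvpva]
    kij_intercept: -0.128
    provenance: "water-PVPVA dispersion correction, constant in T"
  - pair: [water, ind]
    kij_intercept: -0.022
    provenance: "water-IND dispersion correction, constant in T"
  - pair: [pvpva, ind]
    kij_intercept: -0.0621
    provenance: "PVPVA-IND kij fitted to IND solubility in PVPVA, constant in T"
  - pair: [pvp, ind]
    kij_intercept: 0.0922
    kij_slope: -1.18e-04
    provenance: "PVP-IND kij linear in T; printed slope -0.0118/K is a scale slip (|kij|>3), read as -1.18e-4/K giving kij(298.15 K)=0.0570 (see docs/methods.md)"

# Non-equilibrium (glassy) volume parameters.  v0_ne null for the API means
# "use the equilibrium specific volume from the equation of state at the
# reference state (298.15 K, 1 bar)"; the API-water swelling coefficient is
# zero by construction.
ne_params:
  pvp:
    v0_ne: 0.6637
    kw_ne: 0.4279
    provenance: "dry glassy PVP specific volume and water swelling coefficient"
  pvpva:
    v0_ne: 0.7478
    kw_ne: 0.244
    provenance: "dry glassy PVPVA specific volume and water swelling coefficient"
  ind:
    v0_ne: null
    kw_ne: 0.0
    provenance: "API NE volume taken equal to the PC-SAFT equilibrium value; water-API swelling set to zero"

# Segmental Maxwell-Stefan diffusivities of water vs the plasticization
# factor Psi_w at 298.15 K (m^2/s).  Nodes are interpolated piecewise
# linearly and clamped outside the tabulated range.
ms_tables:
  pvp:
    psi: [0.14671, 0.453, 0.70977, 0.91512, 1.10884, 1.34422]
    d_seg: [255.4e-15, 94.7e-15, 57.8e-15, 12.4e-15, 223.6e-15, 345.4e-15]
    provenance: "water-in-PVP segmental MS diffusivity vs plasticization factor, 25 C"
  pvpva:
    psi: [0.07363, 0.27951, 0.50773, 0.74883, 1.01617, 1.40619]
    d_seg: [340.7e-15, 301.5e-15, 75.9e-15, 106.2e-15, 184.3e-15, 610.6e-15]
    provenance: "water-in-PVPVA segmental MS diffusivity vs plasticization factor, 25 C"
  ind:
    psi: [0.05414, 0.2415, 0.48449, 0.777, 1.12032, 1.58168]
    d_seg: [44.8648e-15, 18.5876e-15, 22.2132e-15, 58.6949e-15, 125.916e-15, 166.599e-15]
    provenance: "water-in-IND segmental MS diffusivity vs plasticization factor, 25 C (converted from molecular MS diffusivities)"

# Canonical six-step DVS relative-humidity schedule of the sorption
# experiments (fractions), and default film geometry.
rh_schedule: [0.0924, 0.294, 0.445, 0.599, 0.734, 0.878]
film:
  diameter: 14.5e-3  # m, circular film
  thickness: 8.0e-6  # m, typical dry film thickness
  provenance: "spin-coated film geometry: 14.5 mm circular base, ~7-9 um dry thickness"
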