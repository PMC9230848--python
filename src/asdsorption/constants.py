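"""Physical constants (SI)."""

KB = 1.380649e-23  # Boltzmann constant, J/K
NA = 6.02214076e23  # Avogadro constant, 1/mol
R = KB * NA  # molar gas constant, J/(mol K)

# 1 molecule/Å^3 expressed in molecules/m^3
ANGSTROM3_TO_M3 = 1.0e30
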