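"""Physical constants in the package's internal unit system (nm, ps, kJ/mol)."""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.008314462618

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 298.15

#: k_B T at the default temperature, kJ/mol (~2.4789)
KT_ROOM = KB * DEFAULT_TEMPERATURE

#: Coulomb prefactor f = 1/(4 pi eps0), kJ nm mol^-1 e^-2
COULOMB_CONSTANT = 138.935458
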