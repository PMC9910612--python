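"""Physical constants used throughout the package (SI units)."""

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: Gyromagnetic ratio of phosphorus-31, rad/(s T).
GAMMA_31P = 1.08394e8
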