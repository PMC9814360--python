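"""Physical constants in the package's working units (kJ/mol, nm, e, K)."""

#: Boltzmann constant (= molar gas constant) in kJ mol^-1 K^-1.
KB = 0.008314462618

#: Coulomb constant e^2/(4 pi eps0) in kJ mol^-1 nm e^-2.
KE = 138.935458

#: Relative dielectric used for screened Coulomb interactions between
#: coarse-grained beads (the common CG force-field convention).
DEFAULT_DIELECTRIC = 15.0

#: Default simulation temperature in K.
DEFAULT_TEMPERATURE = 323.0
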