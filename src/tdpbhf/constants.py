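"""Physical constants and unit conversions (CODATA 2018).

All internal quantities are in Hartree atomic units; conversions are applied
only at I/O boundaries (XYZ input in angstrom, spectra reported in eV).
"""

BOHR_PER_ANGSTROM = 1.8897261255
HARTREE_TO_EV = 27.211386245988

# Element symbol -> nuclear charge, for the elements the built-in basis
# registry covers plus the rest of the second period for parsing purposes.
ELEMENT_Z = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
}
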