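"""Unit conversion factors and physical constants.

Every cross-unit conversion in the pipeline goes through this registry so
that factors such as mm^3 -> µm^3 are exact and defined exactly once.
"""

#: cubic millimetres per cubic centimetre
MM3_PER_CM3 = 1.0e3

#: cubic micrometres per cubic millimetre (exact)
UM3_PER_MM3 = 1.0e9

#: attomoles per micromole (exact)
AMOL_PER_UMOL = 1.0e12

#: nanomoles per micromole (exact)
NMOL_PER_UMOL = 1.0e3

#: micrograms per milligram
UG_PER_MG = 1.0e3

#: molar mass of dinitrogen, g/mol (two N atoms)
N2_MOLAR_MASS = 28.0134

#: natural abundance of 15N, atom percent
N15_NATURAL_ABUNDANCE = 0.36782

#: protein copies per femtomole (Avogadro's number / 1e15)
COPIES_PER_FMOL = 6.0221413e8
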