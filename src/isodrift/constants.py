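"""Authoritative physical constants for exact-mass arithmetic.

Monoisotopic atomic masses (Da) from the NIST/CODATA atomic-mass
compilation. Every m/z printed by this package derives from this table;
no other mass values are hard-coded anywhere else.
"""

#: Monoisotopic mass (Da) of the most abundant isotope of each supported element.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.00307400443,
    "O": 15.99491461957,
    "S": 31.9720711744,
    "P": 30.97376199842,
}

#: Masses of the heavy isotopes used as stable-isotope labels.
ISOTOPE_MASS: dict[str, float] = {
    "2H": 2.01410177785,
    "13C": 13.00335483507,
    "15N": 15.00010889888,
}

#: Mass shift (Da) per single isotope substitution.
LABEL_SHIFT: dict[str, float] = {
    "13C": ISOTOPE_MASS["13C"] - MONOISOTOPIC_MASS["C"],
    "15N": ISOTOPE_MASS["15N"] - MONOISOTOPIC_MASS["N"],
    "D": ISOTOPE_MASS["2H"] - MONOISOTOPIC_MASS["H"],
}

#: Proton mass (Da) used for [M-H]-/[M+H]+ arithmetic. This is the mass of a
#: bare proton, i.e. the electron mass is accounted for, which is what
#: reproduces instrument-reported m/z at 4-decimal precision.
PROTON_MASS: float = 1.007276

#: Elements accepted in molecular formulas.
SUPPORTED_ELEMENTS = tuple(MONOISOTOPIC_MASS)
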