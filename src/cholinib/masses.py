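"""Atomic mass tables backing the formula calculus.

Two tables are shipped for the elements that occur in the tetrahydroquinoline
hybrid chemotype and its ESI adducts:

``AVERAGE_WEIGHT``
    IUPAC 2021 standard atomic weights (conventional/abridged values), g/mol.
    Used for "Anal. Calcd." style average molecular weights and elemental
    percentages.

``MONOISOTOPIC_MASS``
    Exact mass of the principal (most abundant) isotope, Da, from the
    AME2020/CODATA evaluation. Used for high-resolution m/z arithmetic;
    ``MONOISOTOPIC_MASS["C"]`` is exactly 12 by definition of the dalton.
"""

from __future__ import annotations

AVERAGE_WEIGHT: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Na": 22.98976928,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Br": 79.904,
}

MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "S": 31.9720711744,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "Br": 78.9183376000,
}

#: Elements accepted by the formula parser.
ALLOWED_ELEMENTS = frozenset(AVERAGE_WEIGHT)

# Electron mass (Da); adduct m/z arithmetic deliberately neglects it
# (0.00055 Da, below the 4-decimal display precision used throughout).
ELECTRON_MASS = 5.48579909e-4
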