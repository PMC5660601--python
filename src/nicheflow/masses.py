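"""Monoisotopic mass constants and negative-mode adduct arithmetic.

FIA-TOF ions measured in negative ionization mode are matched to neutral
metabolites through a small table of adduct mass offsets. Each offset maps a
neutral monoisotopic mass M (Da) to the m/z at which the corresponding anion
is observed. All offsets are composed from IUPAC monoisotopic atomic masses
and the electron mass, so they can be audited element by element.
"""

from __future__ import annotations

from pyteomics import mass as _pt_mass

# IUPAC 2021 monoisotopic atomic masses (Da)
ATOMIC_MASS = {
    "e": 0.000548579909,
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "P": 30.97376151,
    "S": 31.97207069,
}

PROTON = ATOMIC_MASS["H"] - ATOMIC_MASS["e"]

# m/z observed for a neutral of monoisotopic mass M is M + offset.
# Deprotonation ([M-H]-) and fluoride attachment ([M+F]-) are the dominant
# negative-mode ions; H/Na and H/K exchange and NaCl attachment are treated
# as neutral gains followed by deprotonation.
ADDUCT_OFFSETS = {
    "[M-H]-": -PROTON,
    "[M+F]-": ATOMIC_MASS["F"] + ATOMIC_MASS["e"],
    "[M+Na-2H]-": (ATOMIC_MASS["Na"] - ATOMIC_MASS["H"]) - PROTON,
    "[M+K-2H]-": (ATOMIC_MASS["K"] - ATOMIC_MASS["H"]) - PROTON,
    "[M+NaCl-H]-": (ATOMIC_MASS["Na"] + ATOMIC_MASS["Cl"]) - PROTON,
}

DEFAULT_ADDUCTS = tuple(ADDUCT_OFFSETS)


def formula_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a molecular formula such as ``C3H7NO2``."""
    return float(_pt_mass.calculate_mass(formula=formula))


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z at which ``adduct`` of a neutral of the given mass is observed."""
    try:
        return neutral_mass + ADDUCT_OFFSETS[adduct]
    except KeyError:
        raise KeyError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_OFFSETS)}")
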