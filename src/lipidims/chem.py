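"""Monoisotopic mass arithmetic for positive-mode lipid ions.

Provides an elemental-composition parser (deuterium supported, written ``D``
or ``[2H]``), the fixed adduct mass-delta table for singly charged positive
ions (protonated, sodiated, potassiated, dehydrated-protonated and their
one-carbon-13 isotopologues), and neutral-mass builders for the common
glycerophospholipid and sphingomyelin classes used by the synthetic phantom.

Charge-carrier deltas are stored as cation-minus-electron masses so that
``neutral_mass + delta`` is the exact m/z of a +1 ion.
"""

from __future__ import annotations

import re

# CODATA / AME monoisotopic atomic masses, Da
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "D": 2.01410177812,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

# Charge carriers (cation minus electron) and related constants, Da
PROTON = 1.007276
SODIUM_CATION = 22.989218
POTASSIUM_CATION = 38.963158
WATER = 18.010565
C13_DELTA = 1.003355  # 13C - 12C

#: mass delta added to a neutral monoisotopic mass to obtain the +1 ion m/z
ADDUCT_DELTAS: dict[str, float] = {
    "M+H": PROTON,
    "M+Na": SODIUM_CATION,
    "M+K": POTASSIUM_CATION,
    "M+H-H2O": PROTON - WATER,
}
# single-13C isotopologue of every base adduct
ADDUCT_DELTAS.update(
    {f"{label}+13C": delta + C13_DELTA for label, delta in list(ADDUCT_DELTAS.items())}
)

_FORMULA_TOKEN = re.compile(r"(\[2H\]|[A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition such as ``C41H73D7NO8P`` into counts.

    ``D`` and ``[2H]`` both denote deuterium. Raises ``ValueError`` on
    unknown elements or stray characters.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"unparseable formula {formula!r} at position {pos}: "
                f"{formula[pos:match.start()]!r}"
            )
        pos = match.end()
        element = "D" if match.group(1) == "[2H]" else match.group(1)
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"trailing characters in formula {formula!r}: {formula[pos:]!r}")
    if not counts:
        raise ValueError("empty formula")
    return counts


def formula_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of an elemental composition."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of the singly charged positive ion ``adduct`` of a neutral lipid."""
    if adduct not in ADDUCT_DELTAS:
        raise KeyError(
            f"unknown adduct {adduct!r}; known: {sorted(ADDUCT_DELTAS)}"
        )
    return neutral_mass + ADDUCT_DELTAS[adduct]


def _mass(c: int, h: int, n: int, o: int, p: int, d: int = 0) -> float:
    return (
        c * ATOMIC_MASS["C"]
        + h * ATOMIC_MASS["H"]
        + d * ATOMIC_MASS["D"]
        + n * ATOMIC_MASS["N"]
        + o * ATOMIC_MASS["O"]
        + p * ATOMIC_MASS["P"]
    )


def lipid_neutral_mass(
    headgroup: str,
    total_carbons: int,
    total_double_bonds: int,
    *,
    ether: bool = False,
    deuterium: int = 0,
) -> float:
    """Neutral monoisotopic mass of a lipid from class + acyl totals.

    Supported classes: PC, LPC, PE, LPE, SM (sphingoid d-backbone assumed),
    PA. ``ether`` converts one ester linkage to an ether (plasmanyl, O-);
    ``deuterium`` replaces that many hydrogens with deuterium (internal
    standards). Totals are carbons/double bonds summed over all chains,
    i.e. the shorthand notation numbers.
    """
    c, d = total_carbons, total_double_bonds
    if headgroup == "PC":
        counts = (c + 8, 2 * c - 2 * d + 16, 1, 8, 1)
    elif headgroup == "LPC":
        counts = (c + 8, 2 * c - 2 * d + 18, 1, 7, 1)
    elif headgroup == "PE":
        counts = (c + 5, 2 * c - 2 * d + 10, 1, 8, 1)
    elif headgroup == "LPE":
        counts = (c + 5, 2 * c - 2 * d + 12, 1, 7, 1)
    elif headgroup == "SM":
        counts = (c + 5, 2 * c - 2 * d + 13, 2, 6, 1)
    elif headgroup == "PA":
        counts = (c + 3, 2 * c - 2 * d + 5, 0, 8, 1)
    else:
        raise ValueError(f"no mass rule for headgroup {headgroup!r}")
    ch, hh, nn, oo, pp = counts
    if ether:  # one C-O-C linkage instead of an ester: lose one O, gain 2 H
        oo -= 1
        hh += 2
    if deuterium:
        if deuterium > hh:
            raise ValueError("more deuteriums than hydrogens")
        return _mass(ch, hh - deuterium, nn, oo, pp, d=deuterium)
    return _mass(ch, hh, nn, oo, pp)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    return (observed - theoretical) / theoretical * 1e6
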