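"""Elemental formulas and exact ion masses.

Everything downstream of a printed accurate mass starts here: parsing a
Hill-notation formula, summing monoisotopic element masses, and converting a
neutral formula into the m/z of the ion species produced by an APCI source
for GC — the radical molecular cation M+• (charge transfer, "dry" source),
the protonated molecule [M+H]+ (proton transfer, "wet" source), and
in-source fragment cations.

The element mass table is pinned in code (IUPAC 2021 monoisotopic masses of
the lightest isotope, CIAAW) so that results are bit-stable and independent
of the environment. Electron mass is accounted for explicitly in both
species conventions; library m/z values printed to five decimals agree with
this convention to 1e-5 Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "Species",
    "IonDescriptor",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
]

# Monoisotopic (lightest-isotope) masses in Da, IUPAC/CIAAW values.
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.000000000,
    "H": 1.007825032,
    "N": 14.003074004,
    "O": 15.994914620,
    "P": 30.973761998,
    "S": 31.972071174,
    "F": 18.998403163,
    "Cl": 34.968852682,
    "Br": 78.918337600,
    "Si": 27.976926535,
}

#: Mass of a proton, Da (CODATA).
PROTON_MASS = 1.007276466
#: Mass of an electron, Da (CODATA).
ELECTRON_MASS = 0.000548580

# Hill order: C, then H, then all other elements alphabetically.
_HILL_ORDER = {"C": 0, "H": 1}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula text or unsupported element symbol."""


class Species(str, Enum):
    """Ion species kinds formed in the APCI source."""

    MOLECULAR_ION = "molecular_ion"  # M+., charge transfer ("dry")
    PROTONATED = "protonated"        # [M+H]+, proton transfer ("wet")
    FRAGMENT = "fragment"            # in-source fragment cation


@dataclass(frozen=True)
class ElementalFormula:
    """An element→count map; counts are strictly positive integers."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for element, count in self.counts.items():
            if element not in ELEMENT_MASSES:
                raise FormulaError(f"unsupported element symbol: {element!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(
                    f"count for {element} must be a positive integer, got {count!r}"
                )
            clean[element] = count
        if not clean:
            raise FormulaError("empty formula")
        object.__setattr__(self, "counts", dict(clean))

    def __str__(self) -> str:
        return format_formula(self)

    def __contains__(self, element: str) -> bool:
        return element in self.counts

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))


@dataclass(frozen=True)
class IonDescriptor:
    """One ionized species: a formula plus how it acquired its charge.

    For ``Species.FRAGMENT`` the formula is the fragment's own composition,
    not the parent's. ``odd_electron`` selects the fragment convention:
    True (default) means a cation missing one electron (mass − m_e), False
    a protonated even-electron fragment (mass + m_p). It is ignored for the
    other species kinds, whose conventions are fixed.
    """

    formula: ElementalFormula
    species: Species = Species.PROTONATED
    charge: int = 1
    odd_electron: bool = True

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")

    @property
    def mz(self) -> float:
        return ion_mz(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C12H8Cl6O"``.

    Two-letter symbols are matched greedily (``"Cl"`` is chlorine, never
    carbon + lone ``l``). Isotopic labels, charges, parentheses and hydrate
    dots are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        symbol, digits = m.groups()
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(
                f"malformed formula {text!r}: unsupported element {symbol!r}"
            )
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"malformed formula {text!r}: zero count for {symbol}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = m.end()
    return ElementalFormula(counts)


def format_formula(f: ElementalFormula) -> str:
    """Canonical Hill-notation text: C, H, then other elements alphabetically."""
    ordered = sorted(f.counts, key=lambda el: (_HILL_ORDER.get(el, 2), el))
    return "".join(
        el + (str(f.counts[el]) if f.counts[el] > 1 else "") for el in ordered
    )


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Neutral monoisotopic mass in Da: Σ count × lightest-isotope mass."""
    return sum(count * ELEMENT_MASSES[el] for el, count in f.counts.items())


def ion_mz(ion: IonDescriptor) -> float:
    """m/z of an ion under the explicit electron-mass convention.

    M+•        → (M − m_e) / z
    [M+H]+     → (M + m_p) / z   (proton mass already lacks its electron)
    fragment   → odd-electron cation (M − m_e)/z by default, or protonated
                 even-electron fragment when ``odd_electron`` is False.

    Only z = 1 occurs in GC-APCI practice; the charge divisor is kept as
    the extension point for multiply charged ions.
    """
    mass = monoisotopic_mass(ion.formula)
    if ion.species is Species.MOLECULAR_ION:
        ion_mass = mass - ELECTRON_MASS
    elif ion.species is Species.PROTONATED:
        ion_mass = mass + PROTON_MASS
    elif ion.species is Species.FRAGMENT:
        ion_mass = mass - ELECTRON_MASS if ion.odd_electron else mass + PROTON_MASS
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown species {ion.species!r}")
    return ion_mass / ion.charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million: (obs − theo)/theo × 1e6."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6
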