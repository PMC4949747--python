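"""Structural model and mass arithmetic for N-acylphosphatidylethanolamines (NAPEs).

A NAPE is a glycerophosphoethanolamine (PE) carrying a third, amide-linked
fatty acyl chain on the ethanolamine nitrogen.  Shorthand names follow the
pattern ``PE C:D-N-n:dn`` when only the summed O-acyl composition is known
(species level) and ``PE c1:d1/c2:d2-N-n:dn`` when both O-acyl chains are
assigned (molecular-species level).  All mass arithmetic is monoisotopic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

__all__ = [
    "FattyAcyl",
    "AnnotationLevel",
    "NapeSpecies",
    "ElementalComposition",
    "Adduct",
    "ADDUCTS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "parse_name",
    "format_name",
    "composition",
    "pe_body_composition",
    "n_acyl_increment",
    "monoisotopic_mass",
    "ion_mz",
]

_ELEMENTS = ("C", "H", "N", "O", "P")

#: Monoisotopic atomic masses (most abundant isotope), from the NIST table
#: shipped with pyteomics.
MONOISOTOPIC = {el: _pmass.nist_mass[el][0][0] for el in _ELEMENTS}

ELECTRON_MASS = _pmass.nist_mass["e*"][0][0]
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS


class ParseError(ValueError):
    """Raised when a shorthand name cannot be parsed into a valid species."""


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain, ``carbons:double_bonds`` (carbonyl carbon included)."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if not (2 <= self.carbons <= 40):
            raise ValueError(f"acyl carbons must be in [2, 40], got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double bonds must be >= 0, got {self.double_bonds}")
        if self.double_bonds > (self.carbons - 2) // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the maximum "
                f"double-bond count for this chain length"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


class AnnotationLevel(str, Enum):
    """How completely the O-acyl chains are specified."""

    SPECIES = "species"
    MOLECULAR = "molecular"


@dataclass(frozen=True)
class NapeSpecies:
    """One NAPE: a PE body (summed or per-position O-acyls) plus an N-acyl chain."""

    pe_carbons: int
    pe_double_bonds: int
    n_acyl: FattyAcyl
    level: AnnotationLevel = AnnotationLevel.SPECIES
    sn1: Optional[FattyAcyl] = None
    sn2: Optional[FattyAcyl] = None

    def __post_init__(self) -> None:
        if self.pe_carbons < 4:
            raise ValueError(
                f"PE body needs >= 4 O-acyl carbons (two chains of >= 2), "
                f"got {self.pe_carbons}"
            )
        if self.pe_double_bonds < 0:
            raise ValueError("PE double bonds must be >= 0")
        if self.pe_double_bonds > (self.pe_carbons - 4) // 2:
            raise ValueError(
                f"{self.pe_carbons}:{self.pe_double_bonds} exceeds the maximum "
                f"double-bond count for two acyl chains"
            )
        if self.level is AnnotationLevel.MOLECULAR:
            if self.sn1 is None or self.sn2 is None:
                raise ValueError("molecular-level species requires sn1 and sn2")
            if self.sn1.carbons + self.sn2.carbons != self.pe_carbons:
                raise ValueError("sn1 + sn2 carbons must equal pe_carbons")
            if self.sn1.double_bonds + self.sn2.double_bonds != self.pe_double_bonds:
                raise ValueError("sn1 + sn2 double bonds must equal pe_double_bonds")
        else:
            if self.sn1 is not None or self.sn2 is not None:
                raise ValueError("species-level annotation must not carry sn1/sn2")

    @classmethod
    def species(cls, pe_carbons: int, pe_double_bonds: int, n_acyl: FattyAcyl) -> "NapeSpecies":
        return cls(pe_carbons, pe_double_bonds, n_acyl, AnnotationLevel.SPECIES)

    @classmethod
    def molecular(cls, sn1: FattyAcyl, sn2: FattyAcyl, n_acyl: FattyAcyl) -> "NapeSpecies":
        return cls(
            sn1.carbons + sn2.carbons,
            sn1.double_bonds + sn2.double_bonds,
            n_acyl,
            AnnotationLevel.MOLECULAR,
            sn1=sn1,
            sn2=sn2,
        )

    @property
    def total_carbons(self) -> int:
        """All acyl carbons, O-linked plus N-linked (the ECN carbon count)."""
        return self.pe_carbons + self.n_acyl.carbons

    @property
    def total_double_bonds(self) -> int:
        return self.pe_double_bonds + self.n_acyl.double_bonds

    @property
    def name(self) -> str:
        return format_name(self)

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class ElementalComposition:
    """Element -> count map over C, H, N, O, P; supports +/- with negativity guard."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in _ELEMENTS}
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = {el: getattr(self, el) - getattr(other, el) for el in _ELEMENTS}
        if any(v < 0 for v in counts.values()):
            raise ValueError(
                f"subtraction would leave a negative element count: {counts}"
            )
        return ElementalComposition(**counts)

    def as_dict(self) -> dict:
        return {el: getattr(self, el) for el in _ELEMENTS if getattr(self, el)}

    def formula(self) -> str:
        parts = []
        for el in _ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.formula()


# Water and the two phosphate-side neutral losses used in fragment bookkeeping.
H2O = ElementalComposition(H=2, O=1)
H3PO4 = ElementalComposition(H=3, P=1, O=4)
HPO3 = ElementalComposition(H=1, P=1, O=3)


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct; mass_shift includes the electron-mass correction."""

    name: str
    charge: int
    mass_shift: float


ADDUCTS = {
    # [M+H]+: add one proton
    "M+H": Adduct("M+H", +1, PROTON_MASS),
    # [M+NH4]+: add NH3 and a proton
    "M+NH4": Adduct(
        "M+NH4",
        +1,
        MONOISOTOPIC["N"] + 4 * MONOISOTOPIC["H"] - ELECTRON_MASS,
    ),
    # [M-H]-: remove one proton (keep the electron)
    "M-H": Adduct("M-H", -1, -PROTON_MASS),
}


def get_adduct(name: str) -> Adduct:
    key = name.replace("−", "-").replace("‐", "-")
    if key not in ADDUCTS:
        raise KeyError(f"unknown adduct {name!r}; supported: {sorted(ADDUCTS)}")
    return ADDUCTS[key]


# Shorthand grammar.  The typeset literature uses U+2010/U+2011 hyphens, so
# several dash codepoints are normalized to ASCII '-' before matching.
_DASHES = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")
_CHAIN = r"(\d+):(\d+)((?:\([^)]*\))?)"
_NAME_RE = re.compile(
    rf"^PE {_CHAIN}(?:/{_CHAIN})?-N-{_CHAIN}$"
)


def _chain(carbons: str, dbs: str, extra: str, token: str) -> FattyAcyl:
    if extra:
        logger.warning(
            "double-bond position/geometry annotation %r in %r is ignored; "
            "mass arithmetic is position-blind",
            extra,
            token,
        )
    try:
        return FattyAcyl(int(carbons), int(dbs))
    except ValueError as exc:
        raise ParseError(f"invalid acyl token {token!r}: {exc}") from exc


def parse_name(text: str) -> NapeSpecies:
    """Parse a shorthand NAPE name into a :class:`NapeSpecies`.

    Accepts both species-level (``PE 38:2-N-16:0``) and molecular-level
    (``PE 18:1/18:1-N-19:0``) names, with ASCII or typographic hyphens.
    Double-bond position annotations such as ``18:1(9Z)`` are tolerated
    but discarded with a logged warning.
    """
    cleaned = text.strip().translate(_DASHES)
    m = _NAME_RE.match(cleaned)
    if m is None:
        raise ParseError(
            f"cannot parse NAPE name {text!r}; expected 'PE C:D-N-n:dn' or "
            f"'PE c1:d1/c2:d2-N-n:dn'"
        )
    g = m.groups()
    n_acyl = _chain(g[6], g[7], g[8], f"{g[6]}:{g[7]}{g[8]}")
    if g[3] is not None:  # molecular level: sn1/sn2 both given
        sn1 = _chain(g[0], g[1], g[2], f"{g[0]}:{g[1]}{g[2]}")
        sn2 = _chain(g[3], g[4], g[5], f"{g[3]}:{g[4]}{g[5]}")
        try:
            return NapeSpecies.molecular(sn1, sn2, n_acyl)
        except ValueError as exc:
            raise ParseError(f"invalid species {text!r}: {exc}") from exc
    c, d = int(g[0]), int(g[1])
    try:
        return NapeSpecies.species(c, d, n_acyl)
    except ValueError as exc:
        raise ParseError(f"invalid species {text!r}: {exc}") from exc


def format_name(species: NapeSpecies) -> str:
    """Canonical ASCII shorthand for a species; inverse of :func:`parse_name`."""
    if species.level is AnnotationLevel.MOLECULAR:
        body = f"{species.sn1}/{species.sn2}"
    else:
        body = f"{species.pe_carbons}:{species.pe_double_bonds}"
    return f"PE {body}-N-{species.n_acyl}"


def pe_body_composition(pe_carbons: int, pe_double_bonds: int) -> ElementalComposition:
    """Neutral diacyl-PE formula for total O-acyl carbons C and double bonds D."""
    return ElementalComposition(
        C=pe_carbons + 5,
        H=2 * pe_carbons - 2 * pe_double_bonds + 10,
        N=1,
        O=8,
        P=1,
    )


def n_acyl_increment(n_acyl: FattyAcyl) -> ElementalComposition:
    """Composition gained by N-acylating an amine (acyl minus the amide water)."""
    return ElementalComposition(
        C=n_acyl.carbons,
        H=2 * n_acyl.carbons - 2 * n_acyl.double_bonds - 2,
        O=1,
    )


def composition(species: NapeSpecies) -> ElementalComposition:
    """Neutral elemental composition of a NAPE.

    Depends only on (C, D, n, dn): C_(C+n+5) H_(2C-2D+2n-2dn+8) N O9 P,
    i.e. the diacyl-PE body plus the amide-linked N-acyl increment.  All
    molecular species sharing these totals are isobaric structural isomers.
    """
    return pe_body_composition(species.pe_carbons, species.pe_double_bonds) + n_acyl_increment(
        species.n_acyl
    )


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da of a neutral composition."""
    return _pmass.calculate_mass(composition=comp.as_dict()) if comp.as_dict() else 0.0


def ion_mz(comp: ElementalComposition, adduct: Adduct | str) -> float:
    """m/z of the singly charged adduct ion of a neutral composition."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if abs(adduct.charge) != 1:
        raise ValueError("only singly charged adducts are supported")
    return (monoisotopic_mass(comp) + adduct.mass_shift) / abs(adduct.charge)
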