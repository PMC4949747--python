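"""Independent oracles for the test suite.

These deliberately avoid the library's closed-form composition formulas and
its mass table: the molecule is assembled atom by atom from its structural
parts (glycerol backbone, two O-acyl esters, a phosphodiester to
ethanolamine, an amide-linked N-acyl), and masses are summed from a second,
hand-typed table of CODATA/AME monoisotopic atomic masses.
"""

from collections import Counter

# Hand-typed monoisotopic masses (Da), independent of the library's table.
ATOM_MASS = {
    "C": 12.0,
    "H": 1.00782503224,
    "N": 14.00307400446,
    "O": 15.99491461960,
    "P": 30.97376199842,
}
ELECTRON = 0.000548579909
PROTON = ATOM_MASS["H"] - ELECTRON


def fatty_acid_atoms(carbons: int, double_bonds: int) -> Counter:
    """Free fatty acid assembled atom by atom: CH3-(CH2)_(c-2)-COOH."""
    atoms: Counter = Counter()
    atoms["C"] += 1  # terminal methyl carbon
    atoms["H"] += 3
    for _ in range(carbons - 2):  # methylene run
        atoms["C"] += 1
        atoms["H"] += 2
    atoms["C"] += 1  # carboxyl carbon
    atoms["O"] += 2
    atoms["H"] += 1
    for _ in range(double_bonds):  # each C=C removes two hydrogens
        atoms["H"] -= 2
    return atoms


GLYCEROL = Counter({"C": 3, "H": 8, "O": 3})
ETHANOLAMINE = Counter({"C": 2, "H": 7, "N": 1, "O": 1})
PHOSPHORIC_ACID = Counter({"H": 3, "P": 1, "O": 4})
WATER = Counter({"H": 2, "O": 1})


def _condense(*parts: Counter, waters_released: int) -> Counter:
    total: Counter = Counter()
    for p in parts:
        total += p
    total -= Counter({k: v * waters_released for k, v in WATER.items()})
    if any(v < 0 for v in total.values()):
        raise AssertionError("oracle assembly went negative")
    return total


def nape_atoms(sn1: tuple, sn2: tuple, n_acyl: tuple) -> Counter:
    """NAPE from glycerol + 2 O-acyl esters + phosphodiester-ethanolamine
    + amide-linked N-acyl: five condensation waters leave the assembly."""
    return _condense(
        GLYCEROL,
        fatty_acid_atoms(*sn1),
        fatty_acid_atoms(*sn2),
        PHOSPHORIC_ACID,
        ETHANOLAMINE,
        fatty_acid_atoms(*n_acyl),
        waters_released=5,
    )


def diacyl_pe_atoms(sn1: tuple, sn2: tuple) -> Counter:
    return _condense(
        GLYCEROL,
        fatty_acid_atoms(*sn1),
        fatty_acid_atoms(*sn2),
        PHOSPHORIC_ACID,
        ETHANOLAMINE,
        waters_released=4,
    )


def phospho_nae_atoms(n_acyl: tuple) -> Counter:
    """Neutral N-acyl-phosphoethanolamine (the F1 fragment's neutral form)."""
    return _condense(
        PHOSPHORIC_ACID,
        ETHANOLAMINE,
        fatty_acid_atoms(n_acyl[0], n_acyl[1]),
        waters_released=2,
    )


def mass_of(atoms: Counter) -> float:
    return sum(ATOM_MASS[el] * count for el, count in atoms.items())


def protonated_mz(atoms: Counter) -> float:
    return mass_of(atoms) + PROTON
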