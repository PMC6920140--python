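"""Peptide elemental composition and mass arithmetic.

A disulfide-rich peptide such as hepcidin-25 carries four intramolecular
S-S bridges.  Each bridge oxidatively removes two hydrogen atoms from the
reduced peptide, so the intact (oxidised) composition is

    sum(residue formulas) + H2O - 2 * n_disulfides * H

Monoisotopic masses use the lightest-isotope atomic masses; ions are modelled
as proton adducts, ``m/z = (M + z * m_p) / z``, positive mode only.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

__all__ = [
    "ElementalComposition",
    "AminoAcidTable",
    "Peptide",
    "DEFAULT_TABLE",
    "PROTON_MASS",
    "LEGACY_HYDROGEN_MASS",
    "composition_of",
    "monoisotopic_mass",
    "average_mass",
    "mz_of",
    "neutral_mass_from_mz",
]

#: Mass of a proton (positive charge carrier), Da.
PROTON_MASS = 1.00727646688

#: Average-mass hydrogen value used by some legacy fragment calculators for
#: the per-cysteine correction.  Kept for provenance / bit-compatibility;
#: the physically correct monoisotopic H atom is the default everywhere.
LEGACY_HYDROGEN_MASS = 1.00794

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class InvalidSequenceError(ValueError):
    """Raised when a peptide sequence contains an unknown residue letter."""


@dataclass(frozen=True)
class ElementalComposition:
    """Immutable element -> count map, e.g. the C117H172N32O31S8 of hepcidin.

    Zero-count elements are dropped; negative counts are rejected, so
    subtraction that would go below zero raises ``ValueError``.
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", dict(clean))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula string such as ``'C117H172N32O31S8'``."""
        counts: Counter = Counter()
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {pos}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        return cls(counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        c = Counter(self.counts)
        c.update(other.counts)
        return ElementalComposition(c)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        c = Counter(self.counts)
        c.subtract(other.counts)
        if any(v < 0 for v in c.values()):
            raise ValueError(
                f"subtraction below zero: {self.formula()} - {other.formula()}"
            )
        return ElementalComposition(c)

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition({el: c * n for el, c in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts.items())

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = sorted(
            self.counts, key=lambda e: (e != "C", e != "H", e)
        )
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] != 1 else el
            for el in order
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.formula()


# Monoisotopic / average atomic masses (Da), CODATA/IUPAC values.
_ATOMIC_MASSES: Dict[str, Tuple[float, float]] = {
    "H": (1.00782503207, 1.00794),
    "C": (12.0, 12.0107),
    "N": (14.0030740048, 14.0067),
    "O": (15.9949146196, 15.9994),
    "S": (31.97207100, 32.065),
}

# Residue (amino acid minus water) formulas for the 20 standard amino acids.
_RESIDUE_FORMULAS: Dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}


@dataclass(frozen=True)
class AminoAcidTable:
    """Constants behind every mass in the package.

    ``residue_formulas`` holds the 20 standard residues (amino acid minus
    water); termini are closed by one water per peptide.  ``atomic_masses``
    maps element to (monoisotopic, average) Da.
    """

    residue_formulas: Dict[str, ElementalComposition] = field(
        default_factory=lambda: {
            aa: ElementalComposition.from_formula(f)
            for aa, f in _RESIDUE_FORMULAS.items()
        }
    )
    water: ElementalComposition = field(
        default_factory=lambda: ElementalComposition.from_formula("H2O")
    )
    atomic_masses: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_ATOMIC_MASSES)
    )
    proton_mass: float = PROTON_MASS
    #: legacy per-cysteine "proton" value quoted by older fragment calculators
    legacy_hydrogen: float = LEGACY_HYDROGEN_MASS

    def residue(self, letter: str) -> ElementalComposition:
        try:
            return self.residue_formulas[letter]
        except KeyError:
            raise InvalidSequenceError(
                f"unknown residue letter {letter!r}"
            ) from None

    def monoisotopic(self, element: str) -> float:
        try:
            return self.atomic_masses[element][0]
        except KeyError:
            raise KeyError(f"no atomic mass for element {element!r}") from None

    @property
    def hydrogen_mass(self) -> float:
        """Monoisotopic mass of one H atom (disulfide accounting unit)."""
        return self.atomic_masses["H"][0]


DEFAULT_TABLE = AminoAcidTable()


@dataclass(frozen=True)
class Peptide:
    """A peptide with free N/C termini and a count of intramolecular S-S bonds.

    Only the number of disulfides matters for intact mass; connectivity
    (which cysteine pairs) is deliberately not modelled.
    """

    sequence: str
    n_disulfides: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise InvalidSequenceError("empty peptide sequence")
        bad = [c for c in self.sequence if c not in _RESIDUE_FORMULAS]
        if bad:
            raise InvalidSequenceError(
                f"unknown residue letter(s) {sorted(set(bad))!r} in sequence"
            )
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")
        if 2 * self.n_disulfides > self.sequence.count("C"):
            raise ValueError(
                f"{self.n_disulfides} disulfides need "
                f"{2 * self.n_disulfides} cysteines; sequence has "
                f"{self.sequence.count('C')}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_cysteines(self) -> int:
        return self.sequence.count("C")


def composition_of(
    peptide: Peptide, table: AminoAcidTable = DEFAULT_TABLE
) -> ElementalComposition:
    """Elemental composition of an intact peptide.

    Sums the residue formulas, adds one water for the termini, and removes
    two hydrogen atoms per disulfide bridge.
    """
    comp = table.water
    for letter in peptide.sequence:
        comp = comp + table.residue(letter)
    n_h = 2 * peptide.n_disulfides
    if n_h:
        comp = comp - ElementalComposition({"H": n_h})
    return comp


def monoisotopic_mass(
    comp: ElementalComposition, table: AminoAcidTable = DEFAULT_TABLE
) -> float:
    """Monoisotopic mass (Da) of an elemental composition."""
    return sum(n * table.monoisotopic(el) for el, n in comp)


def average_mass(
    comp: ElementalComposition, table: AminoAcidTable = DEFAULT_TABLE
) -> float:
    """Average (chemical) mass in Da; not used by the identification path."""
    return sum(n * table.atomic_masses[el][1] for el, n in comp)


def mz_of(neutral_mass: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """m/z of the z-protonated ion [M + zH]^z+."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * proton_mass) / z


def neutral_mass_from_mz(
    mz: float, z: int, proton_mass: float = PROTON_MASS
) -> float:
    """Neutral mass M from an observed (m/z, z); exact inverse of mz_of."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if mz <= proton_mass:
        raise ValueError(f"m/z {mz} not physical for a protonated ion")
    return z * mz - z * proton_mass
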