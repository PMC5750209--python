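"""Elemental-formula arithmetic and residue mass tables.

All downstream mass bookkeeping — peptides, oligonucleotides, cross-link
neutral losses, fragment ions — reduces to sums over :class:`ElementalFormula`
objects evaluated against an embedded isotope table.  Monoisotopic masses are
the default, matching high-resolution FT-type instruments; average masses are
available for low-resolution work.

Oligonucleotides are assembled from deoxynucleoside-5'-monophosphate residues
with the phosphodiester condensation rule

    mass(N1..Nn) = sum(residue masses) - (n-1) * mass(H2O) + terminal deltas

where the baseline termini are 5'-phosphate / 3'-OH and terminal groups are
expressed as deltas from that baseline (5'-OH removes HPO3; a 3' biotin-TEG
adds a named formula).  Peptides use the standard residue-mass convention
(sum of dehydrated residues + H2O).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ElementalFormula",
    "MassMode",
    "Oligo",
    "PROTON_MASS",
    "parse_formula",
    "parse_oligo_codes",
    "peptide_formula",
    "peptide_mass",
    "oligo_formula",
    "oligo_mass",
    "ion_mz",
    "neutral_from_mz",
    "AMINO_ACID_RESIDUES",
    "NUCLEOTIDE_RESIDUES",
    "NUCLEOBASES",
    "FIVE_PRIME_GROUPS",
    "THREE_PRIME_GROUPS",
    "NAMED_MODS",
    "WATER",
    "HI_LOSS",
]

# Mass of a proton (charged-species arithmetic, not the H atom mass).
PROTON_MASS = 1.007276

# Monoisotopic (most abundant isotope) and average atomic masses, IUPAC.
_MONO = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "I": 126.904473,
    "Br": 78.9183376,
    "Cl": 34.96885271,
    "F": 18.99840320,
    "Na": 22.98976928,
    "K": 38.9637069,
    "Se": 79.9165218,
    "Fe": 55.9349421,
}
_AVG = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "P": 30.973762,
    "S": 32.065,
    # iodine is mononuclidic: its average mass equals the isotope mass
    "I": 126.904473,
    "Br": 79.904,
    "Cl": 35.453,
    "F": 18.9984032,
    "Na": 22.98977,
    "K": 39.0983,
    "Se": 78.96,
    "Fe": 55.845,
}


class MassMode(enum.Enum):
    """Which per-element mass to use when evaluating a formula."""

    monoisotopic = "monoisotopic"
    average = "average"


class FormulaError(ValueError):
    """Raised on unparseable formula strings or invalid element symbols."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> signed count map; the unit of all mass arithmetic.

    A molecule formula has all counts >= 0.  Negative counts are permitted
    only when ``delta`` is True, marking the object as a difference formula
    (e.g. the -HPO3 adjustment for a 5'-OH terminus).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    delta: bool = False

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if el not in _MONO:
                raise FormulaError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n != 0:
                clean[el] = n
        if not self.delta and any(n < 0 for n in clean.values()):
            raise FormulaError(
                "negative element counts require a delta formula"
            )
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged, delta=self.delta or other.delta)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) - n
        # Subtraction may legitimately yield a molecule (all counts >= 0);
        # only flag as delta when a count actually goes negative.
        is_delta = self.delta or other.delta or any(n < 0 for n in merged.values())
        return ElementalFormula(merged, delta=is_delta)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula(
            {el: n * k for el, n in self.counts.items()},
            delta=self.delta or k < 0,
        )

    __rmul__ = __mul__

    def mass(self, mode: MassMode = MassMode.monoisotopic) -> float:
        table = _MONO if mode is MassMode.monoisotopic else _AVG
        return sum(table[el] * n for el, n in self.counts.items())

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        def key(el: str):
            return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

        parts = []
        for el in sorted(self.counts, key=key):
            n = self.counts[el]
            parts.append(el + (str(n) if n != 1 else ""))
        return "".join(parts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d+)?")


def parse_formula(text: str, delta: bool = False) -> ElementalFormula:
    """Parse a flat chemical formula string such as ``"C9H12IN2O8P"``.

    Element symbols with optional (possibly negative, for deltas) integer
    counts; no nesting or parentheses.  The empty string is the empty formula.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"cannot parse formula {text!r} at position {pos}"
            )
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in _MONO:
            raise FormulaError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula(counts, delta=delta)


WATER = parse_formula("H2O")
#: Hydrogen iodide, lost when the 5-iodopyrimidine C5 bonds to a side chain.
HI_LOSS = parse_formula("HI")

# -- residue tables -----------------------------------------------------------

AMINO_ACID_RESIDUES: dict[str, ElementalFormula] = {
    aa: parse_formula(f)
    for aa, f in {
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
    }.items()
}

#: Deoxynucleoside-5'-monophosphate residues (free-acid nucleotide formulas).
NUCLEOTIDE_RESIDUES: dict[str, ElementalFormula] = {
    code: parse_formula(f)
    for code, f in {
        "dA": "C10H14N5O6P",
        "dC": "C9H14N3O7P",
        "dG": "C10H14N5O7P",
        "dT": "C10H15N2O8P",
        "dU": "C9H13N2O8P",
        "5IdU": "C9H12IN2O8P",
        "5BrdU": "C9H12BrN2O8P",
    }.items()
}

#: Free nucleobase formulas; for halogenated pyrimidines this is the parent
#: base (the halogen position becomes the cross-link bond).
NUCLEOBASES: dict[str, ElementalFormula] = {
    "dA": parse_formula("C5H5N5"),
    "dC": parse_formula("C4H5N3O"),
    "dG": parse_formula("C5H5N5O"),
    "dT": parse_formula("C5H6N2O2"),
    "dU": parse_formula("C4H4N2O2"),
    "5IdU": parse_formula("C4H4N2O2"),
    "5BrdU": parse_formula("C4H4N2O2"),
}

_HPO3 = parse_formula("HPO3")

#: 5' terminal groups as deltas from the 5'-phosphate baseline.
FIVE_PRIME_GROUPS: dict[str, ElementalFormula] = {
    "phosphate": ElementalFormula(),
    "OH": ElementalFormula({"H": -1, "P": -1, "O": -3}, delta=True),
}

#: 3' terminal groups as deltas from the 3'-OH baseline.  The biotin-TEG
#: composition (biotin on a triethyleneglycol linker, phosphodiester-attached)
#: is a configurable named group; the shipped value is consistent with
#: vendor 3'-biotin-TEG oligo masses at two-decimal precision.
THREE_PRIME_GROUPS: dict[str, ElementalFormula] = {
    "OH": ElementalFormula(),
    "phosphate": _HPO3,
    "biotin-TEG": parse_formula("C22H40N3O10PS"),
}

#: Named peptide modifications (deltas).
NAMED_MODS: dict[str, ElementalFormula] = {
    "carbamidomethyl": parse_formula("C2H3NO"),
    "oxidation": parse_formula("O"),
}

#: Default fixed modifications: residue -> named mod.  Cysteines are assumed
#: iodoacetamide-alkylated.
DEFAULT_FIXED_MODS: dict[str, str] = {"C": "carbamidomethyl"}

# Per-residue float mass tables: an independent code path from formula
# assembly, kept deliberately separate so the two can be cross-checked.
_AA_MONO = {aa: f.mass(MassMode.monoisotopic) for aa, f in AMINO_ACID_RESIDUES.items()}
_AA_AVG = {aa: f.mass(MassMode.average) for aa, f in AMINO_ACID_RESIDUES.items()}


# -- peptides -----------------------------------------------------------------


def peptide_formula(
    sequence: str,
    fixed_mods: Mapping[str, str] | None = None,
) -> ElementalFormula:
    """Elemental formula of a linear peptide (H- ... -OH termini)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total = total + AMINO_ACID_RESIDUES[aa]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid residue {aa!r} at position {i + 1}"
            ) from None
        if aa in fixed_mods:
            total = total + NAMED_MODS[fixed_mods[aa]]
    return total


def peptide_mass(
    sequence: str,
    fixed_mods: Mapping[str, str] | None = None,
    mode: MassMode = MassMode.monoisotopic,
) -> float:
    """Neutral monoisotopic (or average) mass of a peptide in Da.

    Computed from the per-residue mass table (sum of residues + H2O + mod
    deltas) — a code path independent of :func:`peptide_formula`.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    table = _AA_MONO if mode is MassMode.monoisotopic else _AA_AVG
    total = WATER.mass(mode)
    for i, aa in enumerate(sequence):
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid residue {aa!r} at position {i + 1}"
            ) from None
        if aa in fixed_mods:
            total += NAMED_MODS[fixed_mods[aa]].mass(mode)
    return total


# -- oligonucleotides ---------------------------------------------------------

_OLIGO_TOKEN = re.compile(r"\[([^\]]+)\]|\(([^)]+)\)|([ACGTU])")

_LETTER_CODES = {"A": "dA", "C": "dC", "G": "dG", "T": "dT", "U": "dU"}


def parse_oligo_codes(sequence: str) -> tuple[str, ...]:
    """Tokenize an oligo sequence string into nucleotide codes.

    Plain letters A/C/G/T/U map to the deoxy residues; modified bases are
    written in brackets or parentheses, e.g. ``"GAC[5IdU]T"`` or
    ``"GAC(5IdU)T"``.
    """
    codes: list[str] = []
    pos = 0
    for m in _OLIGO_TOKEN.finditer(sequence):
        if m.start() != pos:
            raise ValueError(
                f"cannot parse oligo sequence {sequence!r} at position {pos}"
            )
        pos = m.end()
        code = m.group(1) or m.group(2) or _LETTER_CODES[m.group(3)]
        if code in _LETTER_CODES:
            code = _LETTER_CODES[code]
        if code not in NUCLEOTIDE_RESIDUES:
            raise ValueError(
                f"unknown nucleotide code {code!r} at position {len(codes) + 1}"
            )
        codes.append(code)
    if pos != len(sequence):
        raise ValueError(
            f"cannot parse oligo sequence {sequence!r} at position {pos}"
        )
    if not codes:
        raise ValueError("empty oligo sequence")
    return tuple(codes)


@dataclass(frozen=True)
class Oligo:
    """A single-stranded DNA oligonucleotide with terminal groups.

    ``codes`` are stored 1-based 5'->3'.  The 3'-anchored position label used
    in bench nomenclature (3'-terminal nucleotide = -1) is available via
    :meth:`position_label`.
    """

    codes: tuple[str, ...]
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        for i, c in enumerate(self.codes):
            if c not in NUCLEOTIDE_RESIDUES:
                raise ValueError(
                    f"unknown nucleotide code {c!r} at position {i + 1}"
                )
        if self.five_prime not in FIVE_PRIME_GROUPS:
            raise ValueError(f"unknown 5' terminal group {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_GROUPS:
            raise ValueError(f"unknown 3' terminal group {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.codes)

    def formula(self) -> ElementalFormula:
        total = ElementalFormula()
        for c in self.codes:
            total = total + NUCLEOTIDE_RESIDUES[c]
        total = total - (len(self.codes) - 1) * WATER
        total = total + FIVE_PRIME_GROUPS[self.five_prime]
        total = total + THREE_PRIME_GROUPS[self.three_prime]
        return total

    def mass(self, mode: MassMode = MassMode.monoisotopic) -> float:
        return self.formula().mass(mode)

    def reactive_positions(self, reactive_codes: Iterable[str]) -> tuple[int, ...]:
        """1-based 5'->3' positions whose code is in ``reactive_codes``."""
        reactive = set(reactive_codes)
        return tuple(
            i + 1 for i, c in enumerate(self.codes) if c in reactive
        )

    def position_label(self, position: int) -> int:
        """Map a 1-based 5'->3' position to the 3'-anchored label.

        The 3'-terminal nucleotide is -1, its 5' neighbour -2, etc.
        """
        if not 1 <= position <= len(self.codes):
            raise ValueError(f"position {position} outside oligo of length {len(self)}")
        return position - len(self.codes) - 1

    def sequence_string(self) -> str:
        parts = []
        for c in self.codes:
            letter = {v: k for k, v in _LETTER_CODES.items()}.get(c)
            parts.append(letter if letter else f"[{c}]")
        return "".join(parts)


def oligo_formula(
    sequence: str | tuple[str, ...],
    five_prime: str = "OH",
    three_prime: str = "OH",
) -> ElementalFormula:
    codes = parse_oligo_codes(sequence) if isinstance(sequence, str) else tuple(sequence)
    return Oligo(codes, five_prime, three_prime).formula()


def oligo_mass(
    sequence: str | tuple[str, ...],
    five_prime: str = "OH",
    three_prime: str = "OH",
    mode: MassMode = MassMode.monoisotopic,
) -> float:
    """Neutral mass of an oligonucleotide chain with the given termini."""
    return oligo_formula(sequence, five_prime, three_prime).mass(mode)


# -- m/z ----------------------------------------------------------------------


def ion_mz(neutral_mass: float, charge: int, polarity: str = "positive") -> float:
    """m/z of a protonated ([M+zH]z+) or deprotonated ([M-zH]z-) species."""
    if charge <= 0:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if polarity == "positive":
        return (neutral_mass + charge * PROTON_MASS) / charge
    if polarity == "negative":
        return (neutral_mass - charge * PROTON_MASS) / charge
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


def neutral_from_mz(mz: float, charge: int, polarity: str = "positive") -> float:
    """Invert :func:`ion_mz`: recover the neutral mass from an observed m/z."""
    if charge <= 0:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    if polarity == "positive":
        return mz * charge - charge * PROTON_MASS
    if polarity == "negative":
        return mz * charge + charge * PROTON_MASS
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
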