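"""Intact heteroconjugate enumeration and neutral-mass matching.

A peptide-DNA heteroconjugate forms when a photoactivatable 5-halopyrimidine
(5-iodo-dU by default) bonds covalently to a proximal aromatic side chain with
loss of the hydrogen halide, so

    mass(conjugate) = mass(peptide) + mass(DNA moiety) - mass(HI)

This module enumerates candidate conjugates from an in-silico digest and
matches them against deconvoluted neutral masses from negative-mode LC/MS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .chem import (
    HI_LOSS,
    ElementalFormula,
    MassMode,
    NUCLEOTIDE_RESIDUES,
    Oligo,
)
from .digest import Peptide

__all__ = [
    "CrossLinkChemistry",
    "Heteroconjugate",
    "MassMatch",
    "conjugate_mass",
    "infer_peptide_mass",
    "search_intact",
]


@dataclass(frozen=True)
class CrossLinkChemistry:
    """Cross-link chemistry: which nucleotide reacts, what is lost, and
    which residues can be hit.

    Defaults model 5-iodo-dU photochemistry: 312 nm UV bonds the pyrimidine
    C5 to an aromatic side chain (F/Y/W/H) with loss of HI.
    """

    reactive_codes: frozenset[str] = frozenset({"5IdU"})
    neutral_loss: ElementalFormula = HI_LOSS
    linkable_residues: frozenset[str] = frozenset("FYWH")

    def __post_init__(self) -> None:
        for code in self.reactive_codes:
            if code not in NUCLEOTIDE_RESIDUES:
                raise ValueError(f"reactive code {code!r} not in nucleotide table")
        if self.neutral_loss.mass() <= 0:
            raise ValueError("neutral-loss mass must be positive")

    def neutral_loss_mass(self, mode: MassMode = MassMode.monoisotopic) -> float:
        return self.neutral_loss.mass(mode)


@dataclass(frozen=True)
class Heteroconjugate:
    """A peptide covalently joined to a DNA moiety (intact oligo or remnant).

    ``reactive_position`` is the 1-based position of the reactive nucleotide
    within the DNA moiety; ``site`` is the optional 1-based cross-linked
    residue index within the peptide.
    """

    peptide: Peptide
    dna: object  # Oligo or remnants.Remnant; both expose .mass(mode)
    reactive_position: int
    site: int | None = None
    neutral_mass: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.site is not None and not 1 <= self.site <= len(self.peptide.sequence):
            raise ValueError(f"site {self.site} outside peptide")


@dataclass(frozen=True)
class MassMatch:
    """An observed neutral mass explained by a candidate heteroconjugate."""

    observed: float
    candidate: Heteroconjugate
    error_da: float
    error_ppm: float


def conjugate_mass(
    peptide_mass: float,
    dna_mass: float,
    chemistry: CrossLinkChemistry | None = None,
    mode: MassMode = MassMode.monoisotopic,
) -> float:
    """Neutral mass of a peptide-DNA heteroconjugate.

    Applies identically whether the DNA moiety is an intact oligonucleotide
    or a nuclease-P1 remnant.
    """
    if chemistry is None:
        chemistry = CrossLinkChemistry()
    if peptide_mass <= 0 or dna_mass <= 0:
        raise ValueError(
            f"masses must be positive (peptide {peptide_mass}, dna {dna_mass})"
        )
    return peptide_mass + dna_mass - chemistry.neutral_loss_mass(mode)


def infer_peptide_mass(
    observed_conjugate: float,
    oligo_mass: float,
    chemistry: CrossLinkChemistry | None = None,
    mode: MassMode = MassMode.monoisotopic,
) -> float:
    """Back-calculate the peptide mass from an observed conjugate mass.

    Inverts :func:`conjugate_mass`; the result is looked up in the digest.
    """
    if chemistry is None:
        chemistry = CrossLinkChemistry()
    result = observed_conjugate - oligo_mass + chemistry.neutral_loss_mass(mode)
    if result <= 0:
        raise ValueError(
            f"no plausible peptide: inferred mass {result:.4f} Da <= 0"
        )
    return result


def search_intact(
    observed_masses: Sequence[float],
    peptides: Sequence[Peptide],
    oligo: Oligo,
    chemistry: CrossLinkChemistry | None = None,
    tolerance: float = 0.3,
    unit: str = "Da",
    mode: MassMode = MassMode.monoisotopic,
) -> list[MassMatch]:
    """Match deconvoluted neutral masses against candidate conjugates.

    Every (observed, peptide, reactive position) combination within tolerance
    is returned, sorted by absolute error ascending, then peptide start
    coordinate.  ``unit`` is ``"Da"`` (absolute, the default — deconvoluted
    intact masses carry more error than fragment m/z) or ``"ppm"``.
    An oligo with several reactive nucleotides yields one candidate per
    reactive position (identical mass, distinct provenance).
    """
    if chemistry is None:
        chemistry = CrossLinkChemistry()
    if unit not in ("Da", "ppm"):
        raise ValueError(f"unit must be 'Da' or 'ppm', got {unit!r}")
    positions = oligo.reactive_positions(chemistry.reactive_codes)
    if not positions:
        return []
    dna_mass = oligo.mass(mode)
    matches = []
    for pep in peptides:
        theo = conjugate_mass(pep.neutral_mass(mode), dna_mass, chemistry, mode)
        for obs in observed_masses:
            err_da = obs - theo
            err_ppm = err_da / theo * 1e6
            err = err_da if unit == "Da" else err_ppm
            if abs(err) <= tolerance:
                for rpos in positions:
                    matches.append(
                        MassMatch(
                            observed=obs,
                            candidate=Heteroconjugate(
                                peptide=pep,
                                dna=oligo,
                                reactive_position=rpos,
                                neutral_mass=theo,
                            ),
                            error_da=err_da,
                            error_ppm=err_ppm,
                        )
                    )
    matches.sort(
        key=lambda m: (
            abs(m.error_da),
            m.candidate.peptide.start,
            m.candidate.peptide.end,
            m.candidate.reactive_position,
        )
    )
    return matches
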