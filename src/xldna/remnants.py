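"""Nuclease-P1 limit products of cross-linked DNA and their precursor ions.

Nuclease P1 trims the DNA moiety of a peptide-DNA heteroconjugate down to the
cross-linked nucleoside 5'-monophosphate; incomplete digestion leaves short
contiguous windows around the reactive position (the observed species include
the mono-nucleotide and the 5'-phosphorylated dinucleotide).  Every remnant is
enumerated as a contiguous window that contains the reactive nucleotide, with
P1-specific termini: 5'-phosphate, 3'-OH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .chem import MassMode, Oligo, ion_mz, oligo_mass
from .conjugates import CrossLinkChemistry, Heteroconjugate, conjugate_mass
from .digest import Peptide

__all__ = ["Remnant", "enumerate_remnants", "remnant_precursors"]


@dataclass(frozen=True, order=True)
class Remnant:
    """A contiguous nucleotide window containing the reactive position.

    ``reactive_index`` is 1-based within the window.  Termini default to the
    P1 limit-product form (5'-phosphate, 3'-OH); phosphate variants and the
    3'-terminal adduct are opt-in at enumeration time.
    """

    codes: tuple[str, ...]
    reactive_index: int
    five_prime: str = "phosphate"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        if not 1 <= self.reactive_index <= len(self.codes):
            raise ValueError("reactive index outside remnant window")

    def __len__(self) -> int:
        return len(self.codes)

    def mass(self, mode: MassMode = MassMode.monoisotopic) -> float:
        return oligo_mass(self.codes, self.five_prime, self.three_prime, mode)

    def label(self) -> str:
        """Display form, e.g. ``p[5IdU]p[dT]`` for the 5'-phosphorylated dimer."""
        parts = []
        for i, c in enumerate(self.codes):
            prefix = "p" if (i > 0 or self.five_prime == "phosphate") else ""
            parts.append(f"{prefix}[{c}]")
        suffix = {"OH": "", "phosphate": "p", "biotin-TEG": "-biotin-TEG"}[
            self.three_prime
        ]
        return "".join(parts) + suffix


def enumerate_remnants(
    oligo: Oligo,
    chemistry: CrossLinkChemistry | None = None,
    max_len: int = 2,
    include_three_prime_adduct: bool = False,
    phosphate_variants: bool = False,
) -> list[Remnant]:
    """All P1 remnant windows of length 1..max_len containing a reactive base.

    Windows are truncated at the oligo boundaries.  When
    ``include_three_prime_adduct`` is set, windows reaching the oligo 3' end
    additionally keep the oligo's named 3' adduct (by default remnants never
    span it — the observed adducts are unmodified nucleotides).
    ``phosphate_variants`` adds +-HPO3 terminal species alongside the
    canonical 5'-phosphate/3'-OH form.
    """
    if chemistry is None:
        chemistry = CrossLinkChemistry()
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    positions = oligo.reactive_positions(chemistry.reactive_codes)
    if not positions:
        raise ValueError("oligo contains no reactive nucleotide")
    out: set[Remnant] = set()
    n = len(oligo)
    for rpos in positions:  # 1-based
        for length in range(1, max_len + 1):
            for start in range(max(1, rpos - length + 1), rpos + 1):
                end = start + length - 1
                if end > n:
                    continue
                codes = oligo.codes[start - 1 : end]
                termini: list[tuple[str, str]] = [("phosphate", "OH")]
                if phosphate_variants:
                    termini += [("OH", "OH"), ("phosphate", "phosphate")]
                if (
                    include_three_prime_adduct
                    and end == n
                    and oligo.three_prime not in ("OH", "phosphate")
                ):
                    termini.append(("phosphate", oligo.three_prime))
                for fp, tp in termini:
                    out.add(
                        Remnant(
                            codes=codes,
                            reactive_index=rpos - start + 1,
                            five_prime=fp,
                            three_prime=tp,
                        )
                    )
    return sorted(out)


def remnant_precursors(
    peptide: Peptide,
    remnants: Iterable[Remnant],
    chemistry: CrossLinkChemistry | None = None,
    charges: Iterable[int] = (1, 2, 3),
    mode: MassMode = MassMode.monoisotopic,
) -> list[tuple[Heteroconjugate, int, float]]:
    """Positive-mode precursor m/z values for peptide + remnant conjugates.

    For each remnant the neutral conjugate is peptide + remnant - neutral
    loss; an [M+zH]z+ m/z is emitted per requested charge.
    """
    if chemistry is None:
        chemistry = CrossLinkChemistry()
    charges = sorted(set(charges))
    if any(z < 1 for z in charges):
        raise ValueError("charges must be positive integers")
    pep_mass = peptide.neutral_mass(mode)
    out = []
    for rem in sorted(remnants):
        neutral = conjugate_mass(pep_mass, rem.mass(mode), chemistry, mode)
        conj = Heteroconjugate(
            peptide=peptide,
            dna=rem,
            reactive_position=rem.reactive_index,
            neutral_mass=neutral,
        )
        for z in charges:
            out.append((conj, z, ion_mz(neutral, z, "positive")))
    return out
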