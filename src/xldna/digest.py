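"""In-silico proteolysis producing candidate peptides with protein coordinates."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chem import MassMode, peptide_mass

__all__ = ["Peptide", "digest", "ENZYMES"]


@dataclass(frozen=True, order=True)
class Peptide:
    """A proteolytic peptide with 1-based inclusive parent coordinates."""

    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates {self.start}-{self.end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )

    def neutral_mass(self, mode: MassMode = MassMode.monoisotopic) -> float:
        return peptide_mass(self.sequence, mode=mode)

    def numbered(self, offset: int = 0) -> str:
        """Display string with residue numbers, e.g. ``L255..K265``.

        ``offset`` shifts coordinates into another numbering scheme (e.g. a
        truncated construct reported in full-length coordinates).
        """
        s, e = self.start + offset, self.end + offset
        return f"{self.sequence[0]}{s}..{self.sequence[-1]}{e}"


def _cleaves_after(protein: str, i: int, after: str, not_before: str) -> bool:
    """True if the enzyme cuts between residues i and i+1 (0-based i)."""
    if protein[i] not in after:
        return False
    if i + 1 < len(protein) and protein[i + 1] in not_before:
        return False
    return True


# Rule table: enzyme id -> (residues cleaved after, residues blocking when next).
ENZYMES: Mapping[str, tuple[str, str]] = {
    "trypsin": ("KR", "P"),
    "trypsin/p": ("KR", ""),
    "lys-c": ("K", ""),
    "glu-c": ("E", "P"),
    "chymotrypsin": ("FWYL", "P"),
}


def cleavage_sites(protein: str, enzyme: str = "trypsin") -> list[int]:
    """0-based indices i such that the enzyme cuts between i and i+1."""
    try:
        after, not_before = ENZYMES[enzyme]
    except KeyError:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; known: {sorted(ENZYMES)}"
        ) from None
    return [
        i
        for i in range(len(protein) - 1)
        if _cleaves_after(protein, i, after, not_before)
    ]


def digest(
    protein: str,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    min_len: int = 5,
    max_len: int = 50,
) -> list[Peptide]:
    """Enumerate proteolytic peptides with up to ``max_missed`` missed cleavages.

    Returns peptides sorted by (start, end); set semantics — each distinct
    peptide appears once.  Length bounds are inclusive; pass ``min_len=1,
    max_len=10**9`` for an unfiltered digest.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    sites = cleavage_sites(protein, enzyme)
    # Fragment boundaries: 0-based start indices of the 0-missed peptides.
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [len(protein)]  # exclusive
    peptides = []
    for a in range(len(starts)):
        for b in range(a, min(a + max_missed + 1, len(starts))):
            seq = protein[starts[a] : ends[b]]
            if not min_len <= len(seq) <= max_len:
                continue
            peptides.append(
                Peptide(
                    start=starts[a] + 1,
                    end=ends[b],
                    sequence=seq,
                    missed_cleavages=b - a,
                )
            )
    return sorted(set(peptides))
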