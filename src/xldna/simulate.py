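"""Ground-truthed synthetic data: intact-mass lists and CID peak lists.

Every stage of the search engine is testable without instrument data by
planting a known cross-link and regenerating what the instrument would have
reported: a deconvoluted neutral-mass list for the intact stage, and a
centroided positive-mode MS/MS peak list for the localization stage.  All
randomness is a pure function of (spec, seed); the generator does not model
isotope envelopes, chromatography, or charge-state intensity distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import MassMode, Oligo, ion_mz, peptide_mass
from .conjugates import CrossLinkChemistry, conjugate_mass
from .digest import Peptide, digest
from .msms import theoretical_fragments
from .remnants import Remnant

__all__ = ["SimulationSpec", "simulate_msms", "simulate_intact"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic CID spectrum.

    ``dropout`` is the per-ion Bernoulli probability that a ladder member is
    missing; ``jitter_ppm`` the Gaussian sigma of the m/z error; noise peaks
    are uniform over [0.9 * min ladder m/z, 1.1 * max ladder m/z] and, by
    default, rejected if they land within ``noise_exclusion_ppm`` of any
    theoretical ion.
    """

    peptide: str
    site: int
    remnant: Remnant
    charges: tuple[int, ...] = (1, 2)
    states: tuple[str, ...] = ("none", "remnant", "base_marker")
    dropout: float = 0.0
    jitter_ppm: float = 0.0
    noise_peaks: int = 0
    noise_exclusion_ppm: float | None = 20.0
    intensity_model: str = "uniform"  # "uniform" | "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError(f"dropout must be in [0, 1], got {self.dropout}")
        if self.jitter_ppm < 0 or self.noise_peaks < 0:
            raise ValueError("jitter and noise counts must be non-negative")
        if self.intensity_model not in ("uniform", "exponential"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")


@dataclass
class MsmsTruth:
    """Ground truth for one simulated spectrum."""

    spec: SimulationSpec
    retained_ions: list  # FragmentIon
    dropped_ions: list
    noise_mz: list[float]
    precursor_mz: float
    precursor_charge: int


def _intensities(rng: np.random.Generator, n: int, model: str) -> np.ndarray:
    # Intensities are cosmetic; annotation ignores them beyond reporting.
    if model == "uniform":
        return rng.uniform(0.1, 1.0, size=n)
    return rng.exponential(1.0, size=n) + 1e-3


def simulate_msms(
    spec: SimulationSpec,
    chemistry: CrossLinkChemistry | None = None,
    mode: MassMode = MassMode.monoisotopic,
) -> tuple[list[tuple[float, float]], MsmsTruth]:
    """Generate one synthetic CID peak list plus its ground-truth record.

    With dropout 0, jitter 0 and no noise the peaks equal the theoretical
    ladder exactly.  Identical (spec, seed) gives identical output.
    """
    if chemistry is None:
        chemistry = CrossLinkChemistry()
    rng = np.random.default_rng(spec.seed)
    ladder = theoretical_fragments(
        spec.peptide, spec.site, spec.remnant,
        charges=spec.charges, states=spec.states, chemistry=chemistry, mode=mode,
    )
    keep = rng.random(len(ladder)) >= spec.dropout
    retained = [ion for ion, k in zip(ladder, keep) if k]
    dropped = [ion for ion, k in zip(ladder, keep) if not k]

    mz = np.array([ion.theoretical_mz for ion in retained])
    if spec.jitter_ppm > 0 and len(mz):
        mz = mz * (1.0 + rng.normal(0.0, spec.jitter_ppm * 1e-6, size=len(mz)))

    theo_mz = np.array([ion.theoretical_mz for ion in ladder])
    lo, hi = 0.9 * theo_mz.min(), 1.1 * theo_mz.max()
    noise: list[float] = []
    excl = spec.noise_exclusion_ppm
    while len(noise) < spec.noise_peaks:
        cand = float(rng.uniform(lo, hi))
        if excl is not None and len(theo_mz):
            if np.min(np.abs(theo_mz - cand) / theo_mz) * 1e6 <= excl:
                continue
        noise.append(cand)

    all_mz = np.concatenate([mz, np.array(noise)]) if noise else mz
    inten = _intensities(rng, len(all_mz), spec.intensity_model)
    order = np.argsort(all_mz)
    peaks = [(float(all_mz[i]), float(inten[i])) for i in order]

    z = max(spec.charges)
    precursor_neutral = conjugate_mass(
        peptide_mass(spec.peptide, mode=mode), spec.remnant.mass(mode), chemistry, mode
    )
    truth = MsmsTruth(
        spec=spec,
        retained_ions=retained,
        dropped_ions=dropped,
        noise_mz=noise,
        precursor_mz=ion_mz(precursor_neutral, z, "positive"),
        precursor_charge=z,
    )
    return peaks, truth


@dataclass
class IntactTruth:
    """Ground truth for one simulated intact-mass list."""

    true_peptide: Peptide
    true_mass: float
    observed_true_mass: float
    decoy_masses: list[float]
    seed: int


def simulate_intact(
    protein: str,
    oligo: Oligo,
    true_peptide: str,
    n_decoys: int = 10,
    sigma_da: float = 0.05,
    seed: int = 0,
    chemistry: CrossLinkChemistry | None = None,
    decoy_exclusion_da: float = 0.5,
    enzyme: str = "trypsin",
    max_missed: int = 2,
    min_len: int = 5,
    max_len: int = 50,
    mode: MassMode = MassMode.monoisotopic,
) -> tuple[list[float], IntactTruth]:
    """Emit a deconvoluted neutral-mass list with one planted conjugate.

    The true peptide's conjugate mass is jittered by N(0, sigma^2); decoys
    are uniform over the candidate mass range but kept at least
    ``max(3 * sigma, decoy_exclusion_da)`` away from every candidate
    conjugate mass, so the planted identity is recoverable by construction.
    """
    if chemistry is None:
        chemistry = CrossLinkChemistry()
    rng = np.random.default_rng(seed)
    peptides = digest(protein, enzyme, max_missed, min_len, max_len)
    matching = [p for p in peptides if p.sequence == true_peptide]
    if not matching:
        raise ValueError(
            f"true peptide {true_peptide!r} not produced by digest of protein"
        )
    true_pep = matching[0]
    dna_mass = oligo.mass(mode)
    candidates = np.array(
        [conjugate_mass(p.neutral_mass(mode), dna_mass, chemistry, mode) for p in peptides]
    )
    true_mass = conjugate_mass(true_pep.neutral_mass(mode), dna_mass, chemistry, mode)
    observed_true = float(true_mass + rng.normal(0.0, sigma_da)) if sigma_da > 0 else true_mass

    exclusion = max(3.0 * sigma_da, decoy_exclusion_da)
    lo, hi = candidates.min() - 50.0, candidates.max() + 50.0
    decoys: list[float] = []
    while len(decoys) < n_decoys:
        cand = float(rng.uniform(lo, hi))
        if np.min(np.abs(candidates - cand)) > exclusion:
            decoys.append(cand)

    masses = sorted([observed_true] + decoys)
    truth = IntactTruth(
        true_peptide=true_pep,
        true_mass=true_mass,
        observed_true_mass=observed_true,
        decoy_masses=decoys,
        seed=seed,
    )
    return masses, truth
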