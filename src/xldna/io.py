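"""File-format adapters, run configuration, and the end-to-end pipeline.

Formats: FASTA for the protein (Biopython), MGF or two-column text (and
optionally mzML) for spectra via pyteomics, TSV with a YAML comment-header
block for all reports, YAML for the run configuration.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from pyteomics import mgf as _mgf

from . import __version__
from .chem import MassMode, Oligo, parse_oligo_codes
from .conjugates import CrossLinkChemistry, search_intact
from .digest import Peptide, digest
from .msms import LocalizationResult, localize
from .remnants import Remnant, enumerate_remnants, remnant_precursors

logger = logging.getLogger("xldna")

__all__ = [
    "RunConfig",
    "parse_oligo_spec",
    "read_fasta",
    "read_mass_list",
    "read_spectra",
    "write_mgf",
    "write_report",
    "read_report",
    "run_pipeline",
    "PipelineResult",
]

_THREE_PRIME_ALIASES = {
    "biotin-teg": "biotin-TEG",
    "biotinteg": "biotin-TEG",
    "oh": "OH",
    "phosphate": "phosphate",
    "p": "phosphate",
}
_FIVE_PRIME_ALIASES = {"oh": "OH", "phosphate": "phosphate", "p": "phosphate"}


def parse_oligo_spec(
    text: str,
    five_prime: str = "OH",
    three_prime: str | None = None,
) -> Oligo:
    """Build an :class:`Oligo` from a sequence spec line.

    Modified bases are bracketed (``[5IdU]``) or parenthesised (``(5IdU)``).
    A trailing ``-Biotin-TEG`` (or other known 3' group) names the 3'
    terminal adduct; alternatively pass ``three_prime`` explicitly.  A
    leading ``P-``/``p-`` marks a 5'-phosphate.  Whitespace is ignored.
    """
    s = "".join(text.split())
    if s.lower().startswith(("p-", "5'p-", "5'-p-")):
        five_prime = "phosphate"
        s = s.split("-", 1)[1]
    for alias, canonical in _THREE_PRIME_ALIASES.items():
        suffix = "-" + alias
        if s.lower().endswith(suffix):
            if three_prime is not None and three_prime != canonical:
                raise ValueError(
                    f"conflicting 3' terminal groups: {three_prime!r} and {canonical!r}"
                )
            three_prime = canonical
            s = s[: -len(suffix)]
            break
    codes = parse_oligo_codes(s)
    return Oligo(
        codes=codes,
        five_prime=_FIVE_PRIME_ALIASES.get(five_prime.lower(), five_prime),
        three_prime=three_prime if three_prime is not None else "OH",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (record id, sequence) pairs; multi-record files are preserved."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_mass_list(path: str | Path) -> list[float]:
    """Neutral masses, one per line or first column of a TSV (mass, intensity)."""
    masses = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            masses.append(float(line.split("\t")[0].split()[0]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: cannot parse mass from {line!r}") from None
    return masses


def _read_peaks_txt(path: Path) -> list[dict]:
    peaks = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace("\t", " ").split()
        try:
            mz = float(parts[0])
            inten = float(parts[1]) if len(parts) > 1 else 1.0
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{lineno}: cannot parse peak from {line!r}") from None
        peaks.append((mz, inten))
    return [
        {
            "title": path.stem,
            "peaks": peaks,
            "precursor_mz": None,
            "precursor_charge": None,
        }
    ]


def read_spectra(path: str | Path) -> list[dict]:
    """Read centroided spectra from MGF, mzML, or two-column text.

    Returns one dict per spectrum with keys ``title``, ``peaks`` (list of
    (m/z, intensity)), ``precursor_mz`` and ``precursor_charge`` (None when
    the format does not carry them).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mgf":
        out = []
        with _mgf.read(str(path)) as reader:
            for spec in reader:
                params = spec.get("params", {})
                charge = params.get("charge")
                charge = int(charge[0]) if charge else None
                pepmass = params.get("pepmass")
                out.append(
                    {
                        "title": params.get("title", f"spectrum_{len(out) + 1}"),
                        "peaks": list(
                            zip(
                                spec["m/z array"].tolist(),
                                spec["intensity array"].tolist(),
                            )
                        ),
                        "precursor_mz": pepmass[0] if pepmass else None,
                        "precursor_charge": charge,
                    }
                )
        return out
    if suffix == ".mzml":
        from pyteomics import mzml as _mzml

        out = []
        with _mzml.read(str(path)) as reader:
            for spec in reader:
                if spec.get("ms level") != 2:
                    continue
                precursor_mz = None
                precursor_charge = None
                try:
                    ion = spec["precursorList"]["precursor"][0][
                        "selectedIonList"
                    ]["selectedIon"][0]
                    precursor_mz = ion.get("selected ion m/z")
                    z = ion.get("charge state")
                    precursor_charge = int(z) if z else None
                except (KeyError, IndexError):
                    pass
                out.append(
                    {
                        "title": spec.get("id", f"spectrum_{len(out) + 1}"),
                        "peaks": list(
                            zip(
                                spec["m/z array"].tolist(),
                                spec["intensity array"].tolist(),
                            )
                        ),
                        "precursor_mz": precursor_mz,
                        "precursor_charge": precursor_charge,
                    }
                )
        return out
    return _read_peaks_txt(path)


def write_mgf(
    path: str | Path,
    spectra: Iterable[dict],
) -> None:
    """Write spectra (dicts as returned by :func:`read_spectra`) as MGF."""
    entries = []
    for spec in spectra:
        mz = [p[0] for p in spec["peaks"]]
        inten = [p[1] for p in spec["peaks"]]
        params = {"title": spec.get("title", "spectrum")}
        if spec.get("precursor_mz") is not None:
            params["pepmass"] = spec["precursor_mz"]
        if spec.get("precursor_charge") is not None:
            params["charge"] = f"{spec['precursor_charge']}+"
        entries.append(
            {"m/z array": mz, "intensity array": inten, "params": params}
        )
    _mgf.write(entries, str(path), file_mode="w")


# -- TSV reports with a YAML header block -------------------------------------


def write_report(path: str | Path, table: pd.DataFrame, meta: dict) -> None:
    """TSV report preceded by a ``#``-commented YAML metadata block."""
    path = Path(path)
    header = yaml.safe_dump(meta, sort_keys=True).rstrip("\n")
    with path.open("w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_report(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Invert :func:`write_report`."""
    import io as _io

    lines = Path(path).read_text().splitlines(keepends=True)
    meta_lines = []
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            meta_lines.append(line[2:])
        elif line.startswith("#"):
            meta_lines.append(line[1:])
        else:
            body_start = i
            break
    table = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    meta = yaml.safe_load("".join(meta_lines)) if meta_lines else {}
    return table, meta


# -- run configuration and pipeline -------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    protein_fasta: str
    oligo_sequence: str
    oligo_five_prime: str = "OH"
    oligo_three_prime: str = "biotin-TEG"
    reactive_codes: tuple[str, ...] = ("5IdU",)
    neutral_loss: str = "HI"
    linkable_residues: str = "FYWH"
    enzyme: str = "trypsin"
    max_missed: int = 2
    min_len: int = 5
    max_len: int = 50
    intact_tolerance_da: float = 0.3
    fragment_tolerance_ppm: float = 20.0
    remnant_max_len: int = 2
    charges: tuple[int, ...] = (1, 2)
    precursor_charges: tuple[int, ...] = (1, 2, 3)
    numbering_offset: int = 0
    output_dir: str = "xldna_out"
    seed: int = 0

    def chemistry(self) -> CrossLinkChemistry:
        from .chem import parse_formula

        return CrossLinkChemistry(
            reactive_codes=frozenset(self.reactive_codes),
            neutral_loss=parse_formula(self.neutral_loss),
            linkable_residues=frozenset(self.linkable_residues),
        )

    def oligo(self) -> Oligo:
        return parse_oligo_spec(
            self.oligo_sequence,
            five_prime=self.oligo_five_prime,
            three_prime=self.oligo_three_prime,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["reactive_codes"] = list(self.reactive_codes)
        d["charges"] = list(self.charges)
        d["precursor_charges"] = list(self.precursor_charges)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("reactive_codes", "charges", "precursor_charges"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Report bundle from one pipeline run."""

    digest_table: pd.DataFrame
    intact_matches: pd.DataFrame
    remnant_table: pd.DataFrame
    localization_table: pd.DataFrame
    localizations: list[LocalizationResult] = field(default_factory=list)
    status: str = "no cross-link"  # "localized" | "ambiguous" | "no cross-link"


def _meta(config: RunConfig, stage: str) -> dict:
    return {
        "tool": "xldna",
        "version": __version__,
        "stage": stage,
        "config_hash": config.digest_hash(),
        "seed": config.seed,
    }


def run_pipeline(
    config: RunConfig,
    intact_masses_path: str | Path | None = None,
    spectra_path: str | Path | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Digest -> intact match -> remnant precursors -> CID localization.

    Reports are written to ``output_dir`` (TSV + YAML header) when given.
    ``status`` is "localized" when at least one spectrum yields an
    unambiguous site, "ambiguous" when candidates tie, and "no cross-link"
    when no conjugate evidence is found (e.g. a control oligo without a
    reactive nucleotide).
    """
    chemistry = config.chemistry()
    oligo = config.oligo()
    mode = MassMode.monoisotopic
    records = read_fasta(config.protein_fasta)

    # Stage 1: digest
    rows = []
    all_peptides: list[Peptide] = []
    for rec_id, seq in records:
        peps = digest(seq, config.enzyme, config.max_missed, config.min_len, config.max_len)
        all_peptides.extend(peps)
        for p in peps:
            rows.append(
                {
                    "protein": rec_id,
                    "peptide": p.sequence,
                    "start": p.start + config.numbering_offset,
                    "end": p.end + config.numbering_offset,
                    "missed_cleavages": p.missed_cleavages,
                    "neutral_mass": p.neutral_mass(mode),
                }
            )
    digest_table = pd.DataFrame(rows)

    # Stage 2: intact matching
    reactive = oligo.reactive_positions(chemistry.reactive_codes)
    intact_rows = []
    if intact_masses_path is not None and reactive:
        observed = read_mass_list(intact_masses_path)
        matches = search_intact(
            observed, all_peptides, oligo, chemistry,
            tolerance=config.intact_tolerance_da, unit="Da", mode=mode,
        )
        for m in matches:
            p = m.candidate.peptide
            intact_rows.append(
                {
                    "observed": m.observed,
                    "peptide": p.sequence,
                    "start": p.start + config.numbering_offset,
                    "end": p.end + config.numbering_offset,
                    "theoretical": m.candidate.neutral_mass,
                    "error_da": m.error_da,
                    "error_ppm": round(m.error_ppm, 1),
                    "reactive_position": m.candidate.reactive_position,
                    "reactive_label": oligo.position_label(
                        m.candidate.reactive_position
                    ),
                }
            )
    intact_matches = pd.DataFrame(
        intact_rows,
        columns=[
            "observed", "peptide", "start", "end", "theoretical",
            "error_da", "error_ppm", "reactive_position", "reactive_label",
        ],
    )

    # Stage 3: remnant precursors for matched peptides
    matched_peptides = []
    seen = set()
    for row in intact_rows:
        key = (row["peptide"], row["start"], row["end"])
        if key not in seen:
            seen.add(key)
            matched_peptides.append(
                next(
                    p for p in all_peptides
                    if p.sequence == row["peptide"]
                    and p.start + config.numbering_offset == row["start"]
                )
            )
    remnant_rows = []
    remnant_list: list[Remnant] = []
    if reactive:
        remnant_list = enumerate_remnants(oligo, chemistry, config.remnant_max_len)
        for pep in matched_peptides:
            for conj, z, mz in remnant_precursors(
                pep, remnant_list, chemistry, config.precursor_charges, mode
            ):
                remnant_rows.append(
                    {
                        "peptide": pep.sequence,
                        "remnant": conj.dna.label(),
                        "remnant_mass": conj.dna.mass(mode),
                        "conjugate_mass": conj.neutral_mass,
                        "charge": z,
                        "mz": mz,
                    }
                )
    remnant_table = pd.DataFrame(
        remnant_rows,
        columns=["peptide", "remnant", "remnant_mass", "conjugate_mass", "charge", "mz"],
    )

    # Stage 4: CID localization, matching each spectrum's precursor (when
    # present) against the remnant-precursor table.
    loc_rows = []
    localizations = []
    if spectra_path is not None and reactive and matched_peptides:
        spectra = read_spectra(spectra_path)
        for spec in spectra:
            pep, rem = _assign_precursor(
                spec, matched_peptides, remnant_list, chemistry,
                config.precursor_charges, mode,
            )
            if pep is None:
                continue
            result = localize(
                pep, rem, spec["peaks"],
                charges=config.charges,
                tol_ppm=config.fragment_tolerance_ppm,
                chemistry=chemistry, mode=mode,
            )
            localizations.append(result)
            best = result.best_site
            loc_rows.append(
                {
                    "spectrum": spec["title"],
                    "peptide": pep.sequence,
                    "remnant": rem.label(),
                    "best_site": (
                        f"{pep.sequence[best - 1]}"
                        f"{pep.start + best - 1 + config.numbering_offset}"
                        if best is not None
                        else "ambiguous:"
                        + ",".join(
                            f"{pep.sequence[s - 1]}"
                            f"{pep.start + s - 1 + config.numbering_offset}"
                            for s in sorted(result.best_sites)
                        )
                    ),
                    "matched_site_determining": max(
                        sc.matched_site_determining for sc in result.scores.values()
                    ),
                    "n_matched_peaks": max(
                        sp.n_matched for sp in result.spectra.values()
                    ),
                    "ambiguous": result.ambiguous,
                }
            )
    localization_table = pd.DataFrame(
        loc_rows,
        columns=[
            "spectrum", "peptide", "remnant", "best_site",
            "matched_site_determining", "n_matched_peaks", "ambiguous",
        ],
    )

    if any(not r["ambiguous"] for r in loc_rows):
        status = "localized"
    elif loc_rows:
        status = "ambiguous"
    else:
        status = "no cross-link"

    result = PipelineResult(
        digest_table=digest_table,
        intact_matches=intact_matches,
        remnant_table=remnant_table,
        localization_table=localization_table,
        localizations=localizations,
        status=status,
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(out / "digest.tsv", digest_table, _meta(config, "digest"))
        write_report(out / "intact_matches.tsv", intact_matches, _meta(config, "intact"))
        write_report(out / "remnant_precursors.tsv", remnant_table, _meta(config, "remnants"))
        write_report(out / "localization.tsv", localization_table, _meta(config, "localize"))
        config.to_yaml(out / "config.yaml")
        logger.info(
            "run complete: status=%s config=%s seed=%d",
            status, config.digest_hash(), config.seed,
        )
    return result


def _assign_precursor(
    spec: dict,
    peptides: Sequence[Peptide],
    remnants: Sequence[Remnant],
    chemistry: CrossLinkChemistry,
    charges: Sequence[int],
    mode: MassMode,
    tol_da: float = 0.02,
):
    """Pick the (peptide, remnant) whose precursor m/z best explains the
    spectrum; falls back to the first candidate when no precursor is given."""
    best = (None, None)
    best_err = None
    for pep in peptides:
        for conj, z, mz in remnant_precursors(pep, remnants, chemistry, charges, mode):
            if spec.get("precursor_mz") is None:
                return pep, conj.dna
            if (
                spec.get("precursor_charge") is not None
                and z != spec["precursor_charge"]
            ):
                continue
            err = abs(mz - spec["precursor_mz"])
            if err <= tol_da and (best_err is None or err < best_err):
                best = (pep, conj.dna)
                best_err = err
    return best
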