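# Methods

## Scope and model

`xldna` implements the computational side of a site-specific protein–DNA
cross-linking MS workflow: a synthetic single-stranded oligo carries one
photoactivatable 5-halopyrimidine (5-iodo-dU); UV irradiation bonds its C5
to a proximal aromatic side chain with loss of the hydrogen halide; the
conjugate is trypsin-digested, observed intact by negative-mode LC/MS, then
nuclease-P1-trimmed and sequenced by positive-mode CID. The package covers
mass bookkeeping, candidate enumeration, matching, and site localization; it
does not model chromatography, isotope envelopes, charge-state deconvolution
of raw spectra, or any wet-lab step.

## Mass arithmetic

Monoisotopic masses are the default (high-resolution instruments); an
average-mass mode exists but none of the shipped defaults depend on it.
Element masses are an embedded IUPAC table (H 1.0078250319, C 12 exactly,
I 126.904473, P 30.97376151, …). The proton mass used for all charged-species
arithmetic is 1.007276 Da. Iodine is mononuclidic, so its average mass is set
equal to its isotope mass rather than the (lower, rounded) standard atomic
weight — this keeps "average ≥ monoisotopic" true for all halogen-bearing
formulas.

Peptides: Σ residue masses + H2O + fixed-modification deltas.
Carbamidomethyl (+C2H3NO) is applied to every cysteine by default, matching
routine iodoacetamide alkylation; the worked peptide contains no cysteine, so
this choice does not affect the shipped examples. Two independent code paths
(per-residue float table vs. elemental-formula assembly) compute peptide
masses and are cross-checked in the tests, along with an external check
against pyteomics.

Oligos: deoxynucleoside-5′-monophosphate residues chained by phosphodiester
condensation, `Σ residues − (n−1)·H2O`, with terminal groups expressed as
deltas from a 5′-phosphate/3′-OH baseline (5′-OH = −HPO3; 3′-phosphate =
+HPO3; named 3′ adducts as formulas).

**Biotin-TEG.** The 3′ biotin-triethyleneglycol adduct used for avidin
enrichment has no published elemental composition from the vendor. The
shipped named group is C22H40N3O10PS (+569.2172 Da relative to 3′-OH),
chosen so that the 20-mer oligos with 5′-OH termini reproduce their reported
intact masses (6867.19 / 6882.19 Da) at the printed two-decimal precision.
It is a configurable table entry, not a constant baked into the code; users
with a vendor composition should override it. Reported intact masses of this
kind carry a few tenths of a Da of bookkeeping slack (whether they are
monoisotopic or average deconvolutions is not always stated), which is why
intact-level matching uses an absolute tolerance rather than ppm.

## Digestion

Trypsin cleaves C-terminal to K/R except before P; the rule table also ships
trypsin/P, Lys-C, Glu-C and chymotrypsin variants. Defaults: ≤2 missed
cleavages, peptide length 5–50. Coordinates are 1-based in the supplied
sequence; a configurable numbering offset lets reports print residue numbers
of a full-length protein when the input is a truncated construct. The
initiator methionine is never auto-removed — the user controls the input
sequence. Digestion is verified against a brute-force oracle that tests every
substring's boundary validity independently.

## Intact matching

`search_intact` matches deconvoluted neutral masses against
`peptide + oligo − HI` for every digest peptide. Default tolerance 0.3 Da
absolute: large-species deconvoluted masses are less accurate than fragment
m/z, and the identification arithmetic this mirrors has ~0.2 Da of slack.
Oligos with several reactive nucleotides yield one candidate per reactive
position (same mass, distinct provenance). Charge-state deconvolution is out
of scope; per-charge m/z values can be converted through the m/z inverse.

## Nuclease-P1 remnants

P1 produces 5′-phosphate/3′-OH products, so every remnant is enumerated in
that canonical form: all contiguous windows of length 1..max_len (default 2,
configurable to 3–4) containing the reactive nucleotide, truncated at oligo
boundaries. The enumeration is symmetric around the reactive position even
though observed dimers suggest the 3′-side linkage resists cleavage — absence
of a theoretical candidate is never the reason a species goes unexplained.
±HPO3 terminal variants are available behind a flag (off: the limit product
is the nucleoside monophosphate). Remnants do not span the 3′ biotin-TEG by
default, since enrichment elutes the material before in-solution P1
digestion; a flag includes adduct-bearing windows.

## CID fragments and localization

b ions are Σ residues(1..i); y ions Σ residues(i+1..n) + H2O; protonated m/z
per requested charge (default 1–2). Site-containing fragments are emitted in
two adduct states:

- `##` (remnant): + remnant − HI. For the mono-nucleotide this equals
  dUMP − 2H, an identity asserted in the tests.
- `#` (base marker): + nucleobase − 2H (uracil → +110.0116 Da), modelling
  glycosidic-bond cleavage with H transfer to the departing sugar. The exact
  H-transfer state is not fixed by first principles, so ±1H variants are
  configurable; the −2H default is the one consistent with the intact
  arithmetic (iodo-base − HI = base − 2H).

a-ions, H2O/NH3 losses and internal ions are off by default (flags exist).

Annotation is greedy best-first within a 20 ppm default tolerance: candidate
(ion, peak) pairs ordered by |ppm error| (computed relative to the observed
peak so that an equidistant peak is a true tie), then lower theoretical m/z,
then peak index; one peak per ion and one ion per peak.

Localization scores every linkable residue (F/Y/W/H). A fragment key
(series, index, charge, state) is *site-determining* when its theoretical m/z
differs by more than the tolerance between at least two candidate sites; for
this chemistry the adduct delta is site-independent, so in practice a key
discriminates by existing under some sites and not others. Each site's score
is its count of matched site-determining ions; the best sites are the argmax,
and ties are reported as ambiguous rather than broken. The score is monotone:
adding a matched site-determining ion for a site never lowers that site's
score.

## Synthetic data

The generator emulates what the instrument software would hand the search
engine, not the instrument itself: centroided positive-mode CID peak lists
(theoretical ladder with per-ion Bernoulli dropout, Gaussian ppm jitter, and
uniform noise peaks over [0.9·min, 1.1·max] of the ladder) and deconvoluted
intact neutral-mass lists (true conjugate with Gaussian Da jitter plus decoy
masses). It does not produce isotope envelopes, charge-state intensity
distributions, co-eluting species, or intensity structure — intensities are
cosmetic — so passing tests demonstrate correct inference under idealized
peak-picking, not robustness to real-spectrum artefacts.

All randomness flows from a single explicit per-spec seed through one
`numpy` generator; identical spec + seed is byte-identical. Noise peaks are
rejection-sampled away from theoretical ions (within the matching tolerance)
unless collisions are explicitly requested, so ground truth stays
unambiguous. Intact decoys are kept `max(3σ, 0.5 Da)` away from every
candidate conjugate mass; the 0.5 Da floor keeps decoys outside any sensible
intact tolerance even when σ is small, making the planted identity
recoverable by construction.

The localization performance check uses 200 replicates at 20% dropout, 5 ppm
jitter and 20 noise peaks per spectrum (seeds 1..200, fragment tolerance
20 ppm) on the 11-residue worked peptide — sizes at which the whole suite
runs in seconds while every ladder position is exercised.

## Numerical and design choices

- Tolerances: intact 0.3 Da absolute; fragments 20 ppm; internal identities
  asserted at 1e-6–1e-9 Da.
- Degenerate inputs fail loudly: empty sequences, unknown residues/codes
  (with position), non-positive masses or charges, oligos without a reactive
  nucleotide where one is required.
- Oligo positions are stored 1-based 5′→3′; the 3′-anchored bench label
  (3′-terminal nucleotide = −1) is a documented mapping used in reports.
- Reports are TSV with a `#`-commented YAML header carrying tool version,
  config hash and seed; equal config + inputs give identical reports.

## Known limitations

- No FDR control (target–decoy is future work); matches are ranked by error
  only.
- No probabilistic localization score; the site call is a count argmax with
  explicit ambiguity, not a calibrated probability.
- RNA remnants and non-halopyrimidine chemistries are expressible through the
  tables but untested.
- mzML support reads MS2 centroid arrays only; vendor raw files are out of
  scope.
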