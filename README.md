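# xldna

A search engine for **site-specific protein–DNA photo-cross-linking mass
spectrometry**. Given a protein sequence, an oligonucleotide carrying a
photoactivatable 5-halopyrimidine (5-iodo-2′-deoxyuridine, 5IdU, by default),
and mass-spectrometric observations, `xldna` identifies peptide–DNA
heteroconjugates and localizes the cross-linked amino acid.

**Who it is for.** Labs mapping protein–DNA contacts by placing 5IdU at a
chosen position of a synthetic oligo, UV-irradiating the complex (312 nm forms
a covalent bond from the pyrimidine C5 to a proximal aromatic side chain with
loss of HI), enriching the conjugates, and characterising them by LC/MS and
CID tandem MS. The manual ion bookkeeping those experiments require is what
this package automates.

## The model

All arithmetic is monoisotopic. For a peptide P, DNA moiety D (intact oligo
or nuclease-P1 remnant) and the hydrogen-halide neutral loss (HI,
127.9123 Da):

```
M(conjugate) = M(P) + M(D) − M(HI)
m/z([M+zH]z+) = (M + z·1.007276)/z          (positive mode)
```

Oligos are chains of deoxynucleoside-5′-monophosphate residues,
`M = Σ residues − (n−1)·M(H2O) + terminal deltas`. Nuclease P1 trims the DNA
moiety of a conjugate to 5′-phosphate/3′-OH windows containing the
cross-linked nucleotide (the limit product is the mono-nucleotide; incomplete
digestion leaves short extensions). In CID, b/y fragments that contain the
cross-linked residue appear with the full remnant minus HI (annotated `##`)
or with only the nucleobase after glycosidic-bond cleavage (`#`, uracil − 2H
= +110.0116 Da); fragments that do not contain it are unmodified. The
cross-link site is the aromatic residue (F/Y/W/H) whose site-determining ions
— fragments whose presence discriminates between candidate sites — are best
matched in the spectrum; ties are reported as ambiguous, never broken.

## Worked example

The tryptic peptide `LDIAFGTHATK` of a DNA 3′-end-processing enzyme
cross-links via its F residue to a 20-mer with 5IdU two nucleotides from the
3′ end (`GTAGAGGATCTAAAAGAC(5IdU)T`, 3′-biotin-TEG):

```
$ xldna mass --peptide LDIAFGTHATK
neutral_mass    1172.6190

$ xldna mass --oligo "GTAGAGGATCTAAAAGAC(5IdU)T-Biotin-TEG"
neutral_mass    6867.1888

$ xldna remnants --oligo "GTAGAGGATCTAAAAGAC(5IdU)T-Biotin-TEG" \
        --peptide LDIAFGTHATK --charges 2,3
p[5IdU]         1478.6443   2+  740.3294
p[5IdU]         1478.6443   3+  493.8887
p[5IdU]p[dT]    1782.6903   2+  892.3524
p[5IdU]p[dT]    1782.6903   3+  595.2374
p[dC]p[5IdU]    1767.6906   2+  884.8526
p[dC]p[5IdU]    1767.6906   3+  590.2375
```

Reading: the peptide (1172.62 Da, i.e. ~1173 Da at unit resolution) plus the
P1 limit product 5-iodo-dUMP minus HI gives a 1478.64 Da conjugate whose
[M+2H]²⁺ is m/z 740.33 and [M+3H]³⁺ is 493.89; the incompletely digested
pU-pT dinucleotide conjugate gives 892.35 / 595.24. An intact-level
identification works the other way round: an observed deconvoluted conjugate
mass of 7912.11 Da minus the oligo (6867.19 Da) plus HI infers a 1172.83 Da
peptide, matching `LDIAFGTHATK` within the 0.3 Da intact tolerance.

The full pipeline (digest → intact match → remnant precursors → CID
localization) runs from a YAML config:

```
xldna run config.yaml --intact-masses masses.tsv --spectra msms.mgf --out results/
```

and writes TSV reports; the localization report names the cross-linked
residue (e.g. `F259` with the configured numbering offset) or flags the
spectrum as ambiguous. `xldna simulate` generates ground-truthed synthetic
spectra for testing any of these stages without instrument data.

## Layout

- `xldna.chem` — elemental formulas, residue tables, mass/m/z conversions
- `xldna.digest` — in-silico proteolysis (trypsin rule table)
- `xldna.conjugates` — intact heteroconjugate masses and matching
- `xldna.remnants` — nuclease-P1 remnant enumeration, precursor m/z
- `xldna.msms` — b/y fragments with `#`/`##` adduct states, annotation,
  site localization
- `xldna.simulate` — ground-truthed synthetic spectra and mass lists
- `xldna.io` / `xldna.cli` — FASTA/MGF/mzML/TSV/YAML adapters, pipeline,
  command line

See `docs/methods.md` for assumptions, parameter defaults, and limitations.
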