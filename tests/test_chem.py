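"""Formula arithmetic, residue tables, and mass/mz conversions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from xldna.chem import (
    ElementalFormula,
    FormulaError,
    MassMode,
    ion_mz,
    neutral_from_mz,
    oligo_mass,
    parse_formula,
    peptide_formula,
    peptide_mass,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestParseFormula:
    @pytest.mark.parametrize(
        "text, counts, mono",
        [
            ("", {}, 0.0),
            ("H2O", {"H": 2, "O": 1}, 18.01056),
            ("HI", {"H": 1, "I": 1}, 127.91230),
            ("C9H12IN2O8P", {"C": 9, "H": 12, "I": 1, "N": 2, "O": 8, "P": 1}, 433.93760),
        ],
    )
    def test_examples(self, text, counts, mono):
        f = parse_formula(text)
        assert dict(f.counts) == counts
        assert f.mass() == pytest.approx(mono, abs=5e-6)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(FormulaError, match="Xx"):
            parse_formula("C2Xx3")

    def test_round_trip_through_canonical_string(self):
        f = parse_formula("O2C9PH12IN2O6")
        assert parse_formula(str(f)) == f

    def test_negative_counts_require_delta(self):
        with pytest.raises(FormulaError):
            ElementalFormula({"H": -1})
        delta = ElementalFormula({"H": -1, "P": -1, "O": -3}, delta=True)
        assert delta.mass() < 0

    @given(
        st.dictionaries(st.sampled_from("CHNOPSI"), st.integers(0, 40), max_size=6),
        st.dictionaries(st.sampled_from("CHNOPSI"), st.integers(0, 40), max_size=6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_mass_linearity(self, a, b):
        fa, fb = ElementalFormula(a), ElementalFormula(b)
        assert math.isclose(
            (fa + fb).mass(), fa.mass() + fb.mass(), abs_tol=1e-9
        )

    @given(st.dictionaries(st.sampled_from("CI"), st.integers(1, 30), min_size=1))
    @settings(max_examples=50, derandomize=True)
    def test_average_at_least_monoisotopic(self, counts):
        f = ElementalFormula(counts)
        assert f.mass(MassMode.average) >= f.mass(MassMode.monoisotopic)


class TestPeptideMass:
    @pytest.mark.parametrize(
        "seq, mono",
        [
            ("LDIAFGTHATK", 1172.619),
            ("G", 75.0320),
        ],
    )
    def test_examples(self, seq, mono):
        assert peptide_mass(seq) == pytest.approx(mono, abs=5e-4)

    def test_rounds_to_the_low_resolution_report(self):
        assert round(peptide_mass("LDIAFGTHATK")) == 1173

    def test_empty_and_unknown_residue(self):
        with pytest.raises(ValueError):
            peptide_mass("")
        with pytest.raises(ValueError, match="position 3"):
            peptide_mass("GAZK")

    @given(st.text(alphabet=AA, min_size=1, max_size=25))
    @settings(max_examples=200, derandomize=True)
    def test_two_code_paths_agree(self, seq):
        """Per-residue mass-table sum vs elemental-formula assembly."""
        assert math.isclose(
            peptide_mass(seq), peptide_formula(seq).mass(), abs_tol=1e-6
        )

    @given(st.text(alphabet=AA.replace("C", ""), min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_pyteomics(self, seq):
        """Independent cross-check against pyteomics' mass machinery
        (cysteine excluded: our default applies carbamidomethyl)."""
        assert math.isclose(
            peptide_mass(seq),
            pyteomics_mass.calculate_mass(sequence=seq),
            abs_tol=1e-4,
        )


class TestOligoMass:
    @pytest.mark.parametrize(
        "seq, mono",
        [
            ("[dT]", 322.0566),
            ("[5IdU]", 433.9376),
            ("[5IdU][dT]", 737.9836),
        ],
    )
    def test_monophosphate_examples(self, seq, mono):
        assert oligo_mass(seq, "phosphate", "OH") == pytest.approx(mono, abs=2e-4)

    def test_unknown_code_positions(self):
        with pytest.raises(ValueError, match="position 2"):
            oligo_mass("A[xx]T", "phosphate", "OH")

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=12),
        st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    @settings(max_examples=100, derandomize=True)
    def test_chain_concatenation_rule(self, a, b):
        """Phosphodiester condensation: concat loses one water."""
        water = parse_formula("H2O").mass()
        assert math.isclose(
            oligo_mass(a + b, "phosphate", "OH"),
            oligo_mass(a, "phosphate", "OH") + oligo_mass(b, "phosphate", "OH") - water,
            abs_tol=1e-9,
        )

    def test_printed_intact_oligo_masses(self, oligo_minus2, oligo_minus3):
        """5'-OH / 3'-biotin-TEG 20-mers reproduce the vendor-style masses."""
        assert round(oligo_minus2.mass(), 2) == 6867.19
        assert round(oligo_minus3.mass(), 2) == 6882.19


class TestMz:
    @pytest.mark.parametrize(
        "neutral, z, pol, mz",
        [
            (1478.6442, 2, "positive", 740.3294),
            (1478.6442, 3, "positive", 493.8887),
            (100.0, 1, "negative", 98.9927),
        ],
    )
    def test_examples(self, neutral, z, pol, mz):
        assert ion_mz(neutral, z, pol) == pytest.approx(mz, abs=5e-5)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            ion_mz(100.0, 0)

    @given(
        st.floats(10.0, 2e4),
        st.integers(1, 6),
        st.sampled_from(["positive", "negative"]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip(self, m, z, pol):
        assert math.isclose(neutral_from_mz(ion_mz(m, z, pol), z, pol), m, abs_tol=1e-9)
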