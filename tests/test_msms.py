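"""CID fragment generation, spectrum annotation, and site localization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xldna.chem import peptide_mass
from xldna.msms import (
    adduct_deltas,
    annotate,
    localize,
    theoretical_fragments,
)
from xldna.simulate import SimulationSpec, simulate_msms

from conftest import PEPTIDE, SITE


def _by_label(ions):
    return {f.label: f for f in ions}


class TestTheoreticalFragments:
    def test_unmodified_b_and_y(self, remnant_mono):
        ions = _by_label(
            theoretical_fragments(PEPTIDE, SITE, remnant_mono, charges=(1,))
        )
        assert ions["b4"].theoretical_mz == pytest.approx(413.2395, abs=5e-4)
        assert ions["y6"].theoretical_mz == pytest.approx(614.3256, abs=5e-4)

    def test_remnant_carrying_y_ion(self, remnant_mono):
        ions = _by_label(
            theoretical_fragments(PEPTIDE, SITE, remnant_mono, charges=(1,))
        )
        y7 = ions["y7##"]
        assert y7.theoretical_mz == pytest.approx(1067.4193, abs=5e-4)
        assert y7.contains_site and y7.adduct_state == "remnant"

    def test_base_marker_delta(self, remnant_mono):
        """# ions carry uracil - 2H (+110.0116 Da) on the peptide fragment."""
        deltas = adduct_deltas(remnant_mono)
        assert deltas["base_marker"] == pytest.approx(110.0116, abs=5e-4)
        shifted = adduct_deltas(remnant_mono, base_marker_h_shift=1)
        assert shifted["base_marker"] - deltas["base_marker"] == pytest.approx(
            1.00783, abs=1e-4
        )

    def test_site_containing_fragments_never_adduct_free(self, remnant_mono):
        for ion in theoretical_fragments(PEPTIDE, SITE, remnant_mono):
            if ion.adduct_state == "none":
                assert not ion.contains_site
            else:
                assert ion.contains_site

    def test_invalid_site_rejected(self, remnant_mono):
        with pytest.raises(ValueError):
            theoretical_fragments(PEPTIDE, 99, remnant_mono)
        with pytest.raises(ValueError, match="not linkable"):
            theoretical_fragments(PEPTIDE, 1, remnant_mono)  # L

    @given(st.integers(1, 3), st.sampled_from(["remnant", "base_marker"]))
    @settings(max_examples=30, derandomize=True)
    def test_by_complementarity(self, remnant_mono, charge, state):
        """neutral(b_i) + neutral(y_{n-i}) - peptide mass is 0 or the adduct
        delta, exactly one per pair."""
        ions = theoretical_fragments(
            PEPTIDE, SITE, remnant_mono, charges=(charge,), states=("none", state)
        )
        pep_mass = peptide_mass(PEPTIDE)
        delta = adduct_deltas(remnant_mono)[state]
        n = len(PEPTIDE)
        by_key = {(f.series, f.index): f.neutral_mass for f in ions}
        for i in range(1, n):
            b = by_key.get(("b", i))
            y = by_key.get(("y", n - i))
            assert b is not None and y is not None
            excess = b + y - pep_mass
            # exactly one of the pair carries the adduct
            assert math.isclose(excess, delta, abs_tol=1e-6)


class TestAnnotate:
    def test_empty_peak_list(self, remnant_mono):
        ions = theoretical_fragments(PEPTIDE, SITE, remnant_mono)
        spec = annotate([], ions, tol_ppm=20)
        assert spec.matches == [] and len(spec.unmatched_theoretical) == len(ions)

    def test_exact_ladder_fully_matched(self, remnant_mono):
        ions = theoretical_fragments(PEPTIDE, SITE, remnant_mono)
        peaks = [(ion.theoretical_mz, 1.0) for ion in ions]
        spec = annotate(peaks, ions, tol_ppm=20)
        assert len(spec.matches) == len(ions)
        assert all(m.error_ppm == 0.0 for m in spec.matches)

    def test_equidistant_peak_goes_to_lower_mz_ion(self, remnant_mono):
        ions = theoretical_fragments(PEPTIDE, SITE, remnant_mono, charges=(1,))
        a, b = ions[0], ions[1]
        mid = (a.theoretical_mz + b.theoretical_mz) / 2
        tol = (b.theoretical_mz - a.theoretical_mz) / mid * 1e6  # generous
        spec = annotate([(mid, 1.0)], [a, b], tol_ppm=tol)
        assert len(spec.matches) == 1
        assert spec.matches[0].ion == a

    def test_one_peak_per_ion_and_vice_versa(self, remnant_mono):
        ions = theoretical_fragments(PEPTIDE, SITE, remnant_mono)
        peaks = [(ion.theoretical_mz, 1.0) for ion in ions[:5]] * 2
        spec = annotate(peaks, ions, tol_ppm=20)
        matched_peaks = [m.peak_index for m in spec.matches]
        matched_ions = [m.ion for m in spec.matches]
        assert len(set(matched_peaks)) == len(matched_peaks)
        assert len(set(matched_ions)) == len(matched_ions)

    def test_negative_tolerance_rejected(self, remnant_mono):
        with pytest.raises(ValueError):
            annotate([], [], tol_ppm=-1)

    def test_all_errors_within_tolerance(self, remnant_mono):
        ions = theoretical_fragments(PEPTIDE, SITE, remnant_mono)
        peaks = [(ion.theoretical_mz * (1 + 8e-6), 1.0) for ion in ions]
        spec = annotate(peaks, ions, tol_ppm=10)
        assert spec.matches and all(abs(m.error_ppm) <= 10 for m in spec.matches)


class TestLocalize:
    def test_noiseless_full_ladder_localizes(self, remnant_mono):
        spec = SimulationSpec(peptide=PEPTIDE, site=SITE, remnant=remnant_mono)
        peaks, _ = simulate_msms(spec)
        result = localize(PEPTIDE, remnant_mono, peaks)
        assert result.best_sites == frozenset({SITE})
        assert not result.ambiguous

    def test_candidates_are_linkable_residues(self, remnant_mono):
        result = localize(PEPTIDE, remnant_mono, [])
        # F at 5, H at 8 in LDIAFGTHATK
        assert result.candidate_sites == (5, 8)

    def test_common_ions_only_yields_ambiguous_tie(self, remnant_mono):
        """A spectrum with no site-determining evidence must tie."""
        frags5 = theoretical_fragments(PEPTIDE, 5, remnant_mono)
        frags8 = theoretical_fragments(PEPTIDE, 8, remnant_mono)
        keys8 = {(f.series, f.index, f.charge, f.adduct_state) for f in frags8}
        common = [
            f
            for f in frags5
            if (f.series, f.index, f.charge, f.adduct_state) in keys8
        ]
        peaks = [(f.theoretical_mz, 1.0) for f in common]
        result = localize(PEPTIDE, remnant_mono, peaks)
        assert result.ambiguous and result.best_sites == frozenset({5, 8})
        assert result.best_site is None

    def test_no_linkable_residue_rejected(self, remnant_mono):
        with pytest.raises(ValueError):
            localize("GGAGGK", remnant_mono, [])

    def test_permutation_invariance(self, remnant_mono):
        spec = SimulationSpec(
            peptide=PEPTIDE, site=SITE, remnant=remnant_mono,
            dropout=0.2, jitter_ppm=5, noise_peaks=20, seed=11,
        )
        peaks, _ = simulate_msms(spec)
        a = localize(PEPTIDE, remnant_mono, peaks)
        b = localize(PEPTIDE, remnant_mono, list(reversed(peaks)))
        assert a.best_sites == b.best_sites
        assert {
            s: sc.matched_site_determining for s, sc in a.scores.items()
        } == {s: sc.matched_site_determining for s, sc in b.scores.items()}

    def test_score_monotone_in_added_evidence(self, remnant_mono):
        """Adding a matched site-determining ion never lowers that site's
        score."""
        frags5 = theoretical_fragments(PEPTIDE, 5, remnant_mono)
        frags8 = theoretical_fragments(PEPTIDE, 8, remnant_mono)
        keys8 = {(f.series, f.index, f.charge, f.adduct_state) for f in frags8}
        determining = [
            f
            for f in frags5
            if (f.series, f.index, f.charge, f.adduct_state) not in keys8
        ]
        peaks = []
        prev = -1
        for f in determining[:6]:
            peaks.append((f.theoretical_mz, 1.0))
            score = localize(PEPTIDE, remnant_mono, peaks).scores[5]
            assert score.matched_site_determining >= prev
            prev = score.matched_site_determining
        assert prev >= 1

    def test_both_remnant_forms_localize_identically(
        self, remnant_mono, remnant_dimer
    ):
        """Mono- and di-nucleotide adduct spectra point at the same F."""
        for rem in (remnant_mono, remnant_dimer):
            peaks, _ = simulate_msms(
                SimulationSpec(peptide=PEPTIDE, site=SITE, remnant=rem)
            )
            assert localize(PEPTIDE, rem, peaks).best_site == SITE
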