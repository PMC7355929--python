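"""Mass arithmetic, isotope patterns, MS/MS matching, and the ID ladder."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oliveauth.annotation import (
    AnnotationEvidence,
    CandidateCompound,
    IsotopePattern,
    MSMSSpectrum,
    assign_level,
    isotope_fit,
    isotope_pattern,
    mass_error,
    monoisotopic_mass,
    msms_similarity,
    mz_deprotonated,
    parse_formula,
    search_candidates,
)
from oliveauth.isotopes import ISOTOPES, PROTON_MASS

# printed reference values for deprotonated marker ions, 4 dp
MARKER_MZ = {
    "C6H6O2": 109.0295,     # catechol
    "C8H10O3": 153.0557,    # hydroxytyrosol
    "C7H8O2": 123.0452,     # methyl-catechol in-source fragment
    "C8H10O2": 137.0608,    # tyrosol
    "C4H6O5": 133.0142,     # L-malic acid
    "C7H12O6": 191.0561,    # quinic acid
    "C15H10O5": 269.0455,   # apigenin
    "C15H10O6": 285.0405,   # kaempferol / luteolin
    "C18H30O2": 277.2173,   # alpha-linolenic acid
    "C18H32O2": 279.2330,   # linoleic acid
    "C18H34O2": 281.2486,   # oleic acid
    "C18H30O3": 293.2122,
    "C18H32O3": 295.2279,
    "C18H30O4": 309.2071,
    "C18H32O4": 311.2228,
    "C17H24O11": 403.1246,  # three secoiridoid isomers
    "C25H28O13": 535.1457,  # comselogoside
    "C25H32O13": 539.1770,  # oleuropein
    "C25H36O13": 543.2083,  # dihydrooleuropein
    "C29H36O15": 623.1981,  # verbascoside / isoacteoside
    "C29H36O16": 639.1931,  # campneoside II
    "C9H8O4": 179.0350,
}


def brute_force_pattern(formula: str) -> list[tuple[float, float]]:
    """Independent multinomial enumeration of all isotopologues.

    Enumerates every isotope composition per element, multiplies the
    multinomial probabilities across elements, and returns raw
    (mass, probability) pairs without any pruning or normalization.
    """
    f = parse_formula(formula)
    per_element = []
    for el, n in f.counts.items():
        isos = ISOTOPES[el]
        combos = []
        for split in itertools.product(range(n + 1), repeat=len(isos) - 1):
            rest = n - sum(split)
            if rest < 0:
                continue
            counts = (rest,) + split
            prob = math.factorial(n)
            mass = 0.0
            for k, (m_iso, ab) in zip(counts, isos):
                prob = prob // math.factorial(k)
                mass += k * m_iso
            prob_f = float(prob)
            for k, (m_iso, ab) in zip(counts, isos):
                prob_f *= ab ** k
            combos.append((mass, prob_f))
        per_element.append(combos)
    result = [(0.0, 1.0)]
    for combos in per_element:
        result = [(m1 + m2, p1 * p2) for m1, p1 in result for m2, p2 in combos]
    return result


class TestMassArithmetic:
    def test_carbon_defines_the_dalton(self):
        assert monoisotopic_mass("C") == 12.0

    def test_water_mass(self):
        assert monoisotopic_mass("H2O") == pytest.approx(18.01056, abs=5e-6)

    @pytest.mark.parametrize("formula,expected", sorted(MARKER_MZ.items()))
    def test_deprotonated_marker_ions_to_4dp(self, formula, expected):
        assert round(mz_deprotonated(formula), 4) == pytest.approx(expected)

    def test_deprotonation_identity(self):
        for formula in MARKER_MZ:
            assert mz_deprotonated(formula) + PROTON_MASS == pytest.approx(
                monoisotopic_mass(formula), abs=1e-12
            )

    def test_no_hydrogen_to_remove(self):
        with pytest.raises(ValueError):
            mz_deprotonated("CO2")

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass("C2U")

    def test_formula_parser_counts(self):
        f = parse_formula("C6H6O2")
        assert f.counts == {"C": 6, "H": 6, "O": 2}
        assert parse_formula("NaCl").counts == {"Na": 1, "Cl": 1}


class TestMassError:
    def test_catechol_worked_example(self):
        """Observed 109.0299 against theoretical catechol gives -0.4 mDa."""
        mda, _ = mass_error(mz_deprotonated("C6H6O2"), 109.0299)
        assert round(mda, 1) == -0.4

    def test_equal_inputs_zero(self):
        assert mass_error(100.0, 100.0) == (0.0, 0.0)

    def test_sign_and_ppm(self):
        mda, ppm = mass_error(100.0, 99.9990)
        assert mda == pytest.approx(1.0)
        assert ppm == pytest.approx(10.0)


class TestIsotopePattern:
    def test_single_carbon(self):
        p = isotope_pattern("C")
        assert p.peaks[0] == (12.0, 100.0)
        ratio = 100.0 * ISOTOPES["C"][1][1] / ISOTOPES["C"][0][1]
        assert p.peaks[1][0] == pytest.approx(13.00335, abs=1e-5)
        assert p.peaks[1][1] == pytest.approx(ratio, rel=1e-9)

    def test_matches_brute_force_enumeration(self):
        """Pattern agrees with direct multinomial enumeration on 10 mDa bins
        (coarser than the internal aggregation grid, so the comparison does
        not depend on how boundary isotopologues are merged)."""
        for formula in ("C6H6O2", "C4H6O5", "CHNOPS"):
            raw = brute_force_pattern(formula)
            grid: dict[int, float] = {}
            for m, p in raw:
                grid[round(m * 100)] = grid.get(round(m * 100), 0.0) + p
            base = max(grid.values())
            expected = {
                k: 100.0 * v / base for k, v in grid.items()
                if 100.0 * v / base >= 0.01
            }
            got: dict[int, float] = {}
            for m, a in isotope_pattern(formula, abundance_threshold=1e-4).peaks:
                got[round(m * 100)] = got.get(round(m * 100), 0.0) + a
            for k, exp in expected.items():
                assert got.get(k, 0.0) == pytest.approx(exp, abs=1e-3)

    def test_probability_mass_conserved_in_oracle(self):
        """Raw isotopologue probabilities sum to one."""
        for formula in ("C6H6O2", "C25H32O13", "C2H5Cl"):
            total = sum(p for _, p in brute_force_pattern(formula))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_a_plus_one_abundance_of_catechol(self):
        p = isotope_pattern("C6H6O2")
        a1 = sum(a for m, a in p.peaks if 0.5 < m - p.peaks[0][0] < 1.5)
        # dominated by 6 x 13C; H and 17O contribute a few hundredths
        assert a1 == pytest.approx(6.6, abs=0.3)

    def test_threshold_truncates_to_base_peak(self):
        p = isotope_pattern("C6H6O2", abundance_threshold=100.0)
        assert len(p.peaks) == 1


class TestIsotopeFit:
    def test_identical_patterns_score_zero(self):
        p = isotope_pattern("C6H6O2")
        assert isotope_fit(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_patterns_score_1000(self):
        a = IsotopePattern(((100.0, 100.0),))
        b = IsotopePattern(((200.0, 100.0),))
        assert isotope_fit(a, b) == pytest.approx(1000.0)

    def test_missing_isotopologue_penalty_grows_with_abundance(self):
        scores = []
        for a1 in (2.0, 10.0, 30.0):
            theo = IsotopePattern(((100.0, 100.0), (101.0, a1)))
            obs = IsotopePattern(((100.0, 100.0),))
            # closed form: cosine of (100, a1) against (100, 0)
            expected = 1000.0 * (1.0 - 100.0 / np.hypot(100.0, a1))
            assert isotope_fit(theo, obs) == pytest.approx(expected, abs=1e-9)
            scores.append(isotope_fit(theo, obs))
        assert scores == sorted(scores)


class TestMSMSSimilarity:
    CATECHOL_FRAGMENTS = (65.0033, 81.0346, 91.0189, 108.0217, 109.0295)

    def test_self_similarity(self):
        s = MSMSSpectrum(tuple((m, 10.0 * (i + 1))
                               for i, m in enumerate(self.CATECHOL_FRAGMENTS)))
        score, n = msms_similarity(s, s)
        assert score == pytest.approx(1.0)
        assert n == 5

    def test_catechol_reference_match_counts_all_fragments(self):
        obs = MSMSSpectrum.from_pairs(
            "65.0033:12;81.0346:30;91.0189:45;108.0217:70;109.0295:100"
        )
        ref = MSMSSpectrum(tuple((m, 1.0) for m in self.CATECHOL_FRAGMENTS))
        _, n = msms_similarity(obs, ref)
        assert n == 5

    def test_no_peaks_within_tolerance(self):
        a = MSMSSpectrum(((100.0, 1.0),))
        b = MSMSSpectrum(((150.0, 1.0),))
        assert msms_similarity(a, b) == (0.0, 0)

    @given(st.lists(
        st.tuples(st.floats(50, 500), st.floats(0.1, 100)),
        min_size=1, max_size=8,
    ))
    @settings(deadline=None, max_examples=50)
    def test_symmetric_and_bounded(self, peaks):
        a = MSMSSpectrum(tuple(peaks))
        b = MSMSSpectrum(((123.4, 5.0), (234.5, 50.0)))
        s_ab, n_ab = msms_similarity(a, b)
        s_ba, n_ba = msms_similarity(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-12)
        assert n_ab == n_ba
        assert 0.0 <= s_ab <= 1.0


class TestCandidateSearch:
    CANDIDATES = [
        CandidateCompound("catechol", "C6H6O2"),
        CandidateCompound("tyrosol", "C8H10O2"),
        CandidateCompound("malic acid", "C4H6O5"),
    ]

    def test_catechol_retained_with_printed_error(self):
        hits = search_candidates(109.0299, None, self.CANDIDATES)
        assert [h.name for h in hits] == ["catechol"]
        assert round(hits[0].mass_error_mda, 1) == -0.4

    def test_far_mass_yields_empty(self):
        assert search_candidates(200.0, None, self.CANDIDATES) == []

    def test_rt_error_rule_drops_isobar(self):
        isobars = [
            CandidateCompound("near", "C15H10O6", predicted_rt=8.0),
            CandidateCompound("far", "C15H10O6", predicted_rt=11.0),
        ]
        hits = search_candidates(285.0405, 8.2, isobars)
        assert [h.name for h in hits] == ["near"]


class TestIdentificationLevels:
    def test_reference_standard_is_level_1(self):
        ev = AnnotationEvidence(reference_standard=True)
        assert assign_level(ev) == "1"

    def test_library_cosine_is_level_2a(self):
        ev = AnnotationEvidence(library_msms_cosine=0.966, exact_mass_match=True)
        assert assign_level(ev) == "2a"

    def test_isomer_ambiguity_downgrades_to_2b(self):
        ev = AnnotationEvidence(
            library_msms_cosine=0.9, isomer_indistinguishable=True,
            exact_mass_match=True,
        )
        assert assign_level(ev) == "2b"

    def test_fragment_count_substitutes_for_intensities(self):
        ev = AnnotationEvidence(
            library_has_intensities=False, n_matched_fragments=3,
            exact_mass_match=True,
        )
        assert assign_level(ev) == "2a"

    def test_in_silico_only_is_level_3(self):
        ev = AnnotationEvidence(
            in_silico_or_literature_msms=True, exact_mass_match=True
        )
        assert assign_level(ev) == "3"

    def test_formula_with_isotope_fit_is_level_4(self):
        ev = AnnotationEvidence(
            unique_formula=True, isotope_fit=9.4, exact_mass_match=True
        )
        assert assign_level(ev) == "4"

    def test_exact_mass_only_is_level_5(self):
        ev = AnnotationEvidence(exact_mass_match=True)
        assert assign_level(ev) == "5"

    def test_no_evidence_raises(self):
        with pytest.raises(ValueError):
            assign_level(AnnotationEvidence())
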