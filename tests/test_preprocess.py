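"""Range restriction, isotopic joining, normalization, threshold filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldikit.errors import NormalizationPeakNotFound, ValidationError
from maldikit.formats import Peak, Spectrum
from maldikit.preprocess import (
    IsoParams,
    IsotopicGroup,
    apply_threshold,
    build_threshold,
    join_isotopic_peaks,
    normalize,
    restrict_range,
)

from _oracles import join_oracle
from conftest import random_spectrum


def spec(*pairs: tuple[float, float]) -> Spectrum:
    return Spectrum("t", tuple(Peak(m, a) for m, a in pairs))


class TestRestrictRange:
    def test_closed_interval_keeps_in_range_peaks_only(self):
        s = spec((750.0, 1), (900.0, 2), (2600.0, 3))
        out = restrict_range(s, 800, 2500)
        assert [p.mz for p in out.peaks] == [900.0]

    def test_range_covering_everything_is_identity(self):
        s = spec((900.0, 2), (1500.0, 3))
        assert restrict_range(s, 800, 2500) == s

    def test_peaks_exactly_at_bounds_are_retained(self):
        s = spec((800.0, 1), (2500.0, 2))
        assert len(restrict_range(s, 800, 2500)) == 2

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError):
            restrict_range(spec((900.0, 1)), 2500, 800)


class TestJoinIsotopicPeaks:
    def test_decreasing_envelope_below_crossover_is_joined(self):
        s = spec((1000.0, 100), (1001.0, 60), (1002.0, 20))
        reduced, groups = join_isotopic_peaks(s, IsoParams(3, 0.1))
        assert reduced.peaks == (Peak(1000.0, 180.0),)
        assert len(groups) == 1 and len(groups[0].members) == 3

    def test_maximum_at_second_member_allowed_above_crossover(self):
        s = spec((2000.0, 50), (2001.0, 70), (2002.0, 40))
        reduced, groups = join_isotopic_peaks(s)
        assert reduced.peaks == (Peak(2000.0, 160.0),)

    def test_increasing_abundance_below_crossover_not_joined(self):
        s = spec((1000.0, 50), (1001.0, 70))
        reduced, groups = join_isotopic_peaks(s)
        assert len(reduced) == 2
        assert all(len(g.members) == 1 for g in groups)

    def test_single_peak_is_identity_with_singleton_group(self):
        s = spec((1500.0, 10))
        reduced, groups = join_isotopic_peaks(s)
        assert reduced == s
        assert groups == [IsotopicGroup(Peak(1500.0, 10), (Peak(1500.0, 10),))]

    def test_group_size_capped_at_max_isotopic_peaks(self):
        s = spec(*((1000.0 + k, 100.0 - 10 * k) for k in range(6)))
        _, groups = join_isotopic_peaks(s, IsoParams(max_isotopic_peaks=4))
        assert max(len(g.members) for g in groups) == 4

    def test_spacing_tested_against_last_member_chain(self):
        # 4 members each ~1 Da apart span ~3 Da from the monoisotopic peak
        s = spec((1000.0, 100), (1001.05, 80), (1002.1, 50), (1003.15, 20))
        reduced, _ = join_isotopic_peaks(s, IsoParams(4, 0.1))
        assert len(reduced) == 1

    def test_total_abundance_conserved_on_random_spectra(self, rng):
        params = IsoParams()
        for _ in range(200):
            s = random_spectrum(rng)
            reduced, _ = join_isotopic_peaks(s, params)
            assert reduced.total_abundance == s.total_abundance

    def test_idempotent_when_reduced_peaks_are_well_separated(self, rng):
        params = IsoParams(iso_delta=0.1)
        for _ in range(50):
            s = random_spectrum(rng)
            reduced, _ = join_isotopic_peaks(s, params)
            gaps = [b.mz - a.mz for a, b in zip(reduced.peaks, reduced.peaks[1:])]
            if all(g > 1 + params.iso_delta for g in gaps):
                again, _ = join_isotopic_peaks(reduced, params)
                assert again == reduced

    def test_greedy_matches_brute_force_enumeration(self, rng):
        params = IsoParams(max_isotopic_peaks=4, iso_delta=0.1)
        for _ in range(150):
            s = random_spectrum(rng, n_peaks=int(rng.integers(1, 13)))
            _, groups = join_isotopic_peaks(s, params)
            expected = join_oracle(list(s.peaks), params)
            assert [list(g.members) for g in groups] == expected

    def test_groups_form_a_partition(self, rng):
        for _ in range(50):
            s = random_spectrum(rng)
            _, groups = join_isotopic_peaks(s)
            flat = [p for g in groups for p in g.members]
            assert flat == list(s.peaks)


class TestNormalize:
    def test_reference_peak_scaled_to_exactly_100(self):
        s = spec((900.0, 40), (1046.5, 250), (1500.0, 75))
        out = normalize(s, 1046.5, 0.3)
        by_mz = {p.mz: p.abundance for p in out.peaks}
        assert by_mz[1046.5] == 100.0
        assert by_mz[900.0] == pytest.approx(16.0)
        assert by_mz[1500.0] == pytest.approx(30.0)

    def test_already_normalized_spectrum_unchanged(self):
        s = spec((1046.5, 100.0), (1500.0, 30.0))
        assert normalize(s, 1046.5, 0.3) == s

    def test_idempotent(self):
        s = spec((900.0, 40), (1046.5, 250))
        once = normalize(s, 1046.5, 0.3)
        assert normalize(once, 1046.5, 0.3) == once

    def test_equidistant_tie_broken_toward_lower_mz(self):
        s = spec((1046.4, 50.0), (1046.6, 200.0))
        out = normalize(s, 1046.5, 0.3)
        assert out.peaks[0].abundance == 100.0
        assert out.peaks[1].abundance == pytest.approx(400.0)

    def test_nearest_candidate_wins(self):
        s = spec((1046.3, 50.0), (1046.55, 200.0))
        out = normalize(s, 1046.5, 0.3)
        assert out.peaks[1].abundance == 100.0

    def test_mz_values_unchanged(self):
        s = spec((900.0, 40), (1046.5, 250))
        out = normalize(s, 1046.5, 0.3)
        assert [p.mz for p in out.peaks] == [900.0, 1046.5]

    def test_absent_reference_peak_signalled(self):
        with pytest.raises(NormalizationPeakNotFound):
            normalize(spec((900.0, 40)), 1046.5, 0.3)

    def test_zero_abundance_reference_rejected(self):
        with pytest.raises(ValidationError, match="zero abundance"):
            normalize(spec((1046.5, 0.0)), 1046.5, 0.3)


class TestThreshold:
    def test_linear_interpolation_between_anchors(self):
        line = build_threshold([(800, 0), (1800, 100)], 800, 2500)
        assert line.value_at(1300.0) == pytest.approx(50.0)

    def test_single_anchor_gives_constant_threshold(self):
        line = build_threshold([(1000, 20)], 800, 2500)
        for mz in (800.0, 1000.0, 2500.0):
            assert line.value_at(mz) == 20.0

    def test_end_values_held_constant_to_range_bounds(self):
        line = build_threshold([(1000, 10), (2000, 30)], 800, 2500)
        assert line.value_at(800.0) == 10.0
        assert line.value_at(2500.0) == 30.0

    def test_six_anchors_accepted_seven_rejected(self):
        six = [(800 + 100 * i, float(i)) for i in range(6)]
        build_threshold(six, 800, 2500)
        with pytest.raises(ValidationError):
            build_threshold(six + [(1900, 9.0)], 800, 2500)

    def test_duplicate_anchor_mz_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_threshold([(1000, 5), (1000, 6)], 800, 2500)

    def test_cut_is_strictly_above(self):
        line = build_threshold([(800, 10)], 800, 2500)
        s = spec((900.0, 10.0), (901.5, 10.1))
        out = apply_threshold(s, line)
        assert [p.abundance for p in out.peaks] == [10.1]

    def test_zero_threshold_keeps_positive_peaks(self, rng):
        line = build_threshold([(800, 0)], 800, 2500)
        s = random_spectrum(rng)
        assert apply_threshold(s, line) == s

    def test_apply_threshold_is_idempotent(self, rng):
        line = build_threshold([(800, 5), (2500, 500)], 800, 2500)
        s = random_spectrum(rng)
        once = apply_threshold(s, line)
        assert apply_threshold(once, line) == once

    @given(bump=st.floats(0, 2000), data=st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_survivor_count_monotone_in_anchor_values(self, bump, data):
        rng = np.random.default_rng(data)
        s = random_spectrum(rng)
        anchors = [(800.0, float(rng.uniform(0, 5000))),
                   (1600.0, float(rng.uniform(0, 5000))),
                   (2500.0, float(rng.uniform(0, 5000)))]
        lo = build_threshold(anchors, 800, 2500)
        hi = build_threshold([(m, t + bump) for m, t in anchors], 800, 2500)
        assert len(apply_threshold(s, hi)) <= len(apply_threshold(s, lo))
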