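"""WGD statistics and decision rules on allele-specific copy-number profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wgdctdna.cn_profile import (
    CNProfile,
    CNSegment,
    EmptyProfileError,
    call_wgd_loh,
    call_wgd_mcn,
    frac_loh,
    fraction_mcn_ge2,
    tumor_ploidy,
)

from conftest import brute_force_stats, profile_from_states, random_profile

MB = 1_000_000


class TestStatistics:
    @pytest.mark.parametrize(
        "states, expected",
        [
            ([(100 * MB, 2, 2)], 1.0),            # fully duplicated genome
            ([(50, 1, 1), (30, 1, 1)], 0.0),      # diploid
            ([(40, 2, 1), (40, 1, 1)], 0.5),      # half the genome with MCN 2
        ],
    )
    def test_fraction_mcn_ge2(self, states, expected):
        assert fraction_mcn_ge2(profile_from_states(states)) == expected

    @pytest.mark.parametrize(
        "states, expected",
        [
            ([(70, 1, 1)], 2.0),
            ([(70, 2, 2)], 4.0),
            ([(50, 2, 1), (50, 1, 1)], 2.5),      # hand-weighted mean
        ],
    )
    def test_tumor_ploidy(self, states, expected):
        assert tumor_ploidy(profile_from_states(states)) == expected

    @pytest.mark.parametrize(
        "states, expected",
        [
            ([(10, 1, 0), (10, 2, 0)], 1.0),
            ([(10, 1, 1)], 0.0),
            ([(25, 2, 0), (75, 1, 1)], 0.25),     # quarter of covered length LOH
        ],
    )
    def test_frac_loh(self, states, expected):
        assert frac_loh(profile_from_states(states)) == expected

    def test_gaps_between_segments_are_excluded(self):
        segs = [CNSegment("1", 0, 10, 2, 1), CNSegment("1", 90, 100, 1, 1)]
        profile = CNProfile("S", segs)
        assert fraction_mcn_ge2(profile) == 0.5  # denominator is covered length only

    def test_empty_profile_raises(self):
        with pytest.raises(EmptyProfileError):
            fraction_mcn_ge2(CNProfile("S", []))
        with pytest.raises(EmptyProfileError):
            tumor_ploidy(CNProfile("S", []))
        with pytest.raises(EmptyProfileError):
            frac_loh(CNProfile("S", []))


class TestValidation:
    def test_non_integer_copy_number_rejected(self):
        with pytest.raises(ValueError):
            CNSegment("1", 0, 10, 2.3, 1)

    def test_major_below_minor_rejected(self):
        with pytest.raises(ValueError):
            CNSegment("1", 0, 10, 1, 2)

    def test_end_not_after_start_rejected(self):
        with pytest.raises(ValueError):
            CNSegment("1", 10, 10, 1, 1)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CNProfile("S", [CNSegment("1", 0, 10, 1, 1), CNSegment("1", 5, 15, 1, 1)])


class TestDecisionRules:
    def test_mcn_boundary_is_strict(self):
        # exactly 50% of the genome with MCN >= 2 stays WGD-
        call = call_wgd_mcn(profile_from_states([(40, 2, 1), (40, 1, 1)]))
        assert call.mcn_fraction == 0.5
        assert not call.is_wgd
        assert call.threshold_used == 0.5

    def test_mcn_just_above_half_is_wgd(self):
        call = call_wgd_mcn(profile_from_states([(51, 2, 1), (49, 1, 1)]))
        assert call.is_wgd

    def test_uniform_tetraploid_is_wgd(self):
        assert call_wgd_mcn(profile_from_states([(100, 2, 2)])).is_wgd

    def test_loh_rule_examples(self):
        assert call_wgd_loh(profile_from_states([(10, 2, 2)])).is_wgd       # ploidy 4 vs 2.5
        assert not call_wgd_loh(profile_from_states([(10, 1, 1)])).is_wgd   # ploidy 2 vs 2.5

    def test_loh_rule_with_loh_lowered_threshold(self):
        # FracLOH 0.2 lowers the boundary to 2.25; ploidy 2.3 is WGD+
        profile = profile_from_states([(20, 2, 0), (30, 2, 1), (50, 1, 1)])
        call = call_wgd_loh(profile)
        assert call.frac_loh == pytest.approx(0.2)
        assert call.ploidy == pytest.approx(2.3)
        assert call.threshold_used == pytest.approx(2.25)
        assert call.is_wgd

    def test_loh_boundary_is_strict(self):
        # ploidy exactly 2.5 - 1.25*FracLOH stays WGD-: 40% (2,0) + 60% (1,1)
        profile = profile_from_states([(40, 2, 0), (60, 1, 1)])
        call = call_wgd_loh(profile)
        assert call.ploidy == pytest.approx(call.threshold_used)
        assert not call.is_wgd


class TestSexChromosomes:
    def test_excluded_by_default_included_on_request(self):
        segs = [CNSegment("1", 0, 100, 1, 1), CNSegment("X", 0, 100, 1, 0)]
        profile = CNProfile("male", segs)
        assert frac_loh(profile) == 0.0
        assert frac_loh(profile, include_sex_chromosomes=True) == 0.5

    @pytest.mark.parametrize("label", ["X", "chrY", "23", "chrx"])
    def test_label_dialects(self, label):
        segs = [CNSegment("1", 0, 10, 1, 1), CNSegment(label, 0, 10, 2, 0)]
        assert fraction_mcn_ge2(CNProfile("S", segs)) == 0.0


class TestProperties:
    def test_matches_per_base_oracle_on_random_profiles(self, rng):
        for i in range(50):
            profile = random_profile(rng, sample_id=f"R{i}")
            mcn, ploidy, floh = brute_force_stats(profile)
            assert fraction_mcn_ge2(profile) == mcn
            assert tumor_ploidy(profile) == ploidy
            assert frac_loh(profile) == floh

    @given(st.integers(min_value=1, max_value=99), st.data())
    @settings(max_examples=40, deadline=None)
    def test_segment_split_invariance(self, cut_fraction, data):
        states = data.draw(
            st.lists(
                st.tuples(
                    st.integers(100, 1000),
                    st.integers(0, 4),
                    st.integers(0, 4),
                ).map(lambda t: (t[0], max(t[1], t[2]), min(t[1], t[2]))),
                min_size=1,
                max_size=5,
            )
        )
        whole = profile_from_states(states)
        # split the first segment at an interior point, all states unchanged
        first = whole.segments[0]
        cut = first.start + max(1, (first.length * cut_fraction) // 100)
        cut = min(cut, first.end - 1)
        split_segs = [
            CNSegment(first.chromosome, first.start, cut, first.major_cn, first.minor_cn),
            CNSegment(first.chromosome, cut, first.end, first.major_cn, first.minor_cn),
            *whole.segments[1:],
        ]
        split = CNProfile(whole.sample_id, split_segs)
        assert fraction_mcn_ge2(split) == pytest.approx(fraction_mcn_ge2(whole), abs=1e-12)
        assert tumor_ploidy(split) == pytest.approx(tumor_ploidy(whole), abs=1e-12)
        assert frac_loh(split) == pytest.approx(frac_loh(whole), abs=1e-12)
        assert call_wgd_mcn(split).is_wgd == call_wgd_mcn(whole).is_wgd
        assert call_wgd_loh(split).is_wgd == call_wgd_loh(whole).is_wgd

    def test_doubling_monotonicity(self, rng):
        for i in range(30):
            profile = random_profile(rng, sample_id=f"D{i}")
            doubled = CNProfile(
                profile.sample_id,
                [
                    CNSegment(s.chromosome, s.start, s.end, 2 * s.major_cn, 2 * s.minor_cn)
                    for s in profile.segments
                ],
            )
            assert fraction_mcn_ge2(doubled) >= fraction_mcn_ge2(profile)
            assert tumor_ploidy(doubled) == 2.0 * tumor_ploidy(profile)
            if all(s.major_cn >= 1 for s in profile.segments):
                assert call_wgd_mcn(doubled).is_wgd

    def test_invariant_to_segment_order_and_chromosome_names(self, rng):
        profile = random_profile(rng)
        perm = rng.permutation(len(profile.segments))
        renamed = CNProfile(
            profile.sample_id,
            [
                CNSegment(
                    f"ctg{profile.segments[i].chromosome}",
                    profile.segments[i].start,
                    profile.segments[i].end,
                    profile.segments[i].major_cn,
                    profile.segments[i].minor_cn,
                )
                for i in perm
            ],
        )
        assert fraction_mcn_ge2(renamed) == fraction_mcn_ge2(profile)
        assert frac_loh(renamed) == frac_loh(profile)
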