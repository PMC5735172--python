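"""Profiling: densities, modified/unmodified splits, tail statistics, peaks."""

import numpy as np
import pandas as pd
import pytest

from exorace import (
    build_profile,
    detect_peaks,
    split_modified,
    tail_composition,
    tail_length_boxstats,
    tailing_fractions,
)


def calls_frame(rows):
    """rows: (end_reported, tail_seq, status)"""
    return pd.DataFrame(
        [
            {
                "read_id": f"r{i}",
                "target": "ets_pp1",
                "end_reported": end,
                "tail_seq": tail,
                "tail_len": len(tail),
                "status": status,
                "discard_reason": "",
            }
            for i, (end, tail, status) in enumerate(rows)
        ],
        columns=[
            "read_id", "target", "end_reported", "tail_seq",
            "tail_len", "status", "discard_reason",
        ],
    )


class TestBuildProfile:
    def test_single_position_gets_all_density(self):
        calls = calls_frame([(176, "", "unmodified")] * 10)
        profile = build_profile(calls, "ets_pp1", (170, 180))
        assert profile.density[profile.positions == 176] == 1.0
        assert profile.density.sum() == 1.0

    def test_empty_calls_give_zero_profile(self):
        profile = build_profile(calls_frame([]), "ets_pp1", (1, 10))
        assert profile.counts.sum() == 0
        assert profile.density.sum() == 0.0

    def test_out_of_range_calls_stay_in_denominator(self):
        calls = calls_frame([(176, "", "unmodified")] * 8 + [(500, "", "unmodified")] * 2)
        profile = build_profile(calls, "ets_pp1", (170, 180))
        assert profile.n_retained == 10
        assert profile.density.sum() == pytest.approx(0.8)

    def test_discarded_calls_excluded(self):
        calls = calls_frame([(176, "", "unmodified"), (176, "", "discarded")])
        profile = build_profile(calls, "ets_pp1", (170, 180))
        assert profile.n_retained == 1


class TestSplitModified:
    def test_partition_conserves_counts(self):
        calls = calls_frame(
            [(161, "AA", "modified")] * 3
            + [(161, "", "unmodified")] * 5
            + [(176, "A", "modified")] * 2
        )
        joint = build_profile(calls, "ets_pp1", (155, 190))
        unmod, mod = split_modified(calls, "ets_pp1", (155, 190))
        np.testing.assert_array_equal(unmod.counts + mod.counts, joint.counts)
        np.testing.assert_allclose(unmod.density + mod.density, joint.density)

    def test_all_unmodified_gives_empty_modified_profile(self):
        calls = calls_frame([(161, "", "unmodified")] * 4)
        _, mod = split_modified(calls, "ets_pp1", (155, 190))
        assert mod.counts.sum() == 0

    def test_modified_profile_supported_only_at_tailed_positions(self):
        # mirrors tails being added only to specific intermediates
        calls = calls_frame(
            [(161, "AAA", "modified")] * 5
            + [(168, "", "unmodified")] * 5
            + [(176, "AA", "modified")] * 5
            + [(186, "", "unmodified")] * 5
        )
        _, mod = split_modified(calls, "ets_pp1", (155, 190))
        supported = set(mod.positions[mod.counts > 0])
        assert supported == {161, 176}


class TestTailingStatistics:
    def test_fraction_ge1(self):
        calls = calls_frame(
            [(161, "A", "modified")] * 2 + [(161, "", "unmodified")] * 8
        )
        summary = tailing_fractions(calls)
        assert summary.fraction_ge1 == pytest.approx(0.2)

    def test_all_single_nt_tails_give_zero_ge2(self):
        calls = calls_frame([(161, "A", "modified")] * 4)
        summary = tailing_fractions(calls)
        assert summary.fraction_ge1 == 1.0
        assert summary.fraction_ge2 == 0.0

    def test_fraction_ge2_never_exceeds_ge1(self):
        calls = calls_frame(
            [(161, "A", "modified"), (161, "AAAA", "modified"), (161, "", "unmodified")]
        )
        summary = tailing_fractions(calls)
        assert summary.fraction_ge2 <= summary.fraction_ge1 <= 1.0

    def test_composition_counts_pooled_nucleotides(self):
        calls = calls_frame([(161, "AA", "modified"), (161, "AG", "modified")])
        comp = tail_composition(calls, min_len=2)
        assert comp["A"] == pytest.approx(0.75)
        assert comp["G"] == pytest.approx(0.25)

    def test_composition_undefined_without_tails_in_class(self):
        calls = calls_frame([(161, "A", "modified")])
        assert tail_composition(calls, min_len=2) is None


class TestBoxStats:
    def test_median_of_odd_sample(self):
        assert tail_length_boxstats([1, 2, 3, 4, 5]).median == 3

    def test_far_value_flagged_outlier(self):
        box = tail_length_boxstats([1, 1, 1, 30])
        # linear-interpolation quartiles: q1=1, q3=8.25, fence=19.125
        assert box.q3 == pytest.approx(8.25)
        assert list(box.outliers) == [30]
        assert box.whisker_high == 1

    def test_single_value_degenerate_box(self):
        box = tail_length_boxstats([7])
        assert box.median == box.q1 == box.q3 == 7
        assert box.outliers.size == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tail_length_boxstats([])


class TestDetectPeaks:
    def test_flat_zero_profile_has_no_peaks(self):
        profile = build_profile(calls_frame([]), "ets_pp1", (1, 50))
        assert detect_peaks(profile) == []

    def test_single_dominant_position(self):
        calls = calls_frame([(176, "", "unmodified")] * 10)
        profile = build_profile(calls, "ets_pp1", (170, 180))
        peaks = detect_peaks(profile)
        assert [p.label for p in peaks] == ["P176"]

    def test_four_peak_profile_recovers_canonical_labels(self):
        rows = []
        for pos, n in ((161, 30), (168, 25), (176, 35), (186, 40)):
            rows += [(pos, "", "unmodified")] * n
        rows += [(pos, "", "unmodified") for pos in range(140, 200, 3)]  # shot noise
        profile = build_profile(calls_frame(rows), "ets_pp1", (140, 200))
        labels = [p.label for p in detect_peaks(profile, min_density=0.05)]
        assert labels == ["P161", "P168", "P176", "P186"]

    def test_peaks_sorted_ascending(self):
        calls = calls_frame([(186, "", "unmodified")] * 5 + [(161, "", "unmodified")] * 5)
        profile = build_profile(calls, "ets_pp1", (155, 190))
        positions = [p.position for p in detect_peaks(profile)]
        assert positions == sorted(positions) == [161, 186]
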