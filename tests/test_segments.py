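"""Tests of the donor-run segment caller."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_map
from oracles import brute_force_runs
from ctcnt import segments
from ctcnt.types import DONOR, MISSING, RECIPIENT, GenotypeTrack, ValidationError


def track_of(states, clone_id="c"):
    return GenotypeTrack(clone_id=clone_id, states=np.asarray(states, dtype=np.int8))


def as_tuples(segs):
    return sorted((s.start, s.end, s.length, s.n_support) for s in segs)


class TestCallSegments:
    def test_all_recipient_is_empty(self):
        m = make_map([100, 200, 300])
        assert segments.call_segments(track_of([0, 0, 0]), m) == []

    def test_three_site_run_between_recipient_flanks(self):
        m = make_map([500, 1_000, 1_600, 2_200, 3_000], genome_length=5_000)
        segs = segments.call_segments(
            track_of([RECIPIENT, DONOR, DONOR, DONOR, RECIPIENT]), m
        )
        assert as_tuples(segs) == [(1_000, 2_200, 1_201, 3)]

    def test_short_run_discarded_strictly(self):
        """A 2-site run with hull 401 bp does not exceed the 500 nt cutoff."""
        m = make_map([500, 1_000, 1_400, 3_000], genome_length=5_000)
        segs = segments.call_segments(
            track_of([RECIPIENT, DONOR, DONOR, RECIPIENT]), m
        )
        assert segs == []

    def test_exactly_501_is_kept(self):
        m = make_map([1_000, 1_500], genome_length=5_000, circular=False)
        assert as_tuples(segments.call_segments(track_of([1, 1]), m)) == [
            (1_000, 1_500, 501, 2)
        ]
        m2 = make_map([1_000, 1_499], genome_length=5_000, circular=False)
        assert segments.call_segments(track_of([1, 1]), m2) == []

    def test_isolated_donor_site_fails_seed(self):
        m = make_map([500, 5_000, 9_000], genome_length=10_000)
        assert segments.call_segments(track_of([0, 1, 0]), m) == []

    def test_missing_sites_are_transparent(self):
        """Missing calls neither interrupt a run nor add support."""
        m = make_map([1_000, 1_500, 2_000, 2_500], genome_length=10_000)
        segs = segments.call_segments(
            track_of([DONOR, MISSING, DONOR, RECIPIENT]), m
        )
        assert as_tuples(segs) == [(1_000, 2_000, 1_001, 2)]

    def test_recipient_site_interrupts(self):
        m = make_map([1_000, 2_000, 3_000, 4_000, 5_000, 6_000], genome_length=10_000)
        segs = segments.call_segments(track_of([1, 1, 0, 1, 1, 0]), m)
        assert as_tuples(segs) == [(1_000, 2_000, 1_001, 2), (4_000, 5_000, 1_001, 2)]

    def test_circular_merge_across_origin(self):
        m = make_map([500, 1_000, 5_000, 9_000, 9_500], genome_length=10_000)
        segs = segments.call_segments(track_of([1, 1, 0, 1, 1]), m)
        # run 9,000-9,500 continues through the origin into 500-1,000
        assert as_tuples(segs) == [(9_000, 1_000, 2_001, 4)]

    def test_linear_override_disables_merge(self):
        m = make_map([500, 1_000, 5_000, 9_000, 9_500], genome_length=10_000)
        segs = segments.call_segments(track_of([1, 1, 0, 1, 1]), m, circular=False)
        assert as_tuples(segs) == [(500, 1_000, 501, 2), (9_000, 9_500, 501, 2)]

    def test_track_map_mismatch_raises(self):
        m = make_map([100, 200])
        with pytest.raises(ValidationError):
            segments.call_segments(track_of([1]), m)

    def test_max_interrupts_relaxation(self):
        m = make_map([1_000, 2_000, 3_000, 4_000, 5_000], genome_length=10_000,
                     circular=False)
        strict = segments.call_segments(track_of([1, 1, 0, 1, 1]), m)
        relaxed = segments.call_segments(track_of([1, 1, 0, 1, 1]), m, max_interrupts=1)
        assert len(strict) == 2
        assert as_tuples(relaxed) == [(1_000, 5_000, 4_001, 4)]

    def test_monotonicity_in_min_length(self):
        rng = np.random.default_rng(7)
        m = make_map(np.cumsum(rng.integers(1, 200, size=300)), circular=False)
        track = track_of(rng.choice([0, 1, -1], p=[0.5, 0.4, 0.1], size=300))
        prev_n, prev_total = np.inf, np.inf
        for min_length in (0, 200, 500, 2_000, 10_000):
            segs = segments.call_segments(track, m, min_length=min_length)
            total = sum(s.length for s in segs)
            assert len(segs) <= prev_n and total <= prev_total
            prev_n, prev_total = len(segs), total

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.booleans(),
        st.integers(2, 3),
        st.sampled_from([0, 100, 500]),
    )
    def test_matches_brute_force_oracle(self, seed, circular, min_seed, min_length):
        """Caller output equals an explicit per-site scan on random tracks."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        positions = np.cumsum(rng.integers(1, 300, size=n))
        G = int(positions[-1] + rng.integers(1, 500))
        m = make_map(positions, genome_length=G, circular=circular)
        track = track_of(rng.choice([0, 1, -1], p=[0.4, 0.45, 0.15], size=n))
        called = segments.call_segments(
            track, m, min_seed=min_seed, min_length=min_length
        )
        expected = brute_force_runs(
            positions, track.states, G, circular, min_seed, min_length
        )
        assert as_tuples(called) == sorted(expected)


class TestMatchTruth:
    def test_empty_truth_and_calls(self):
        m = make_map([100, 200])
        from ctcnt.types import CloneTruth

        report = segments.match_truth([], CloneTruth("c", []), m)
        assert len(report.matches) == 0
        assert report.false_calls == []

    def test_single_marker_planting_undetectable(self):
        from ctcnt.types import CloneTruth

        m = make_map([1_000, 5_000, 9_000], genome_length=10_000)
        truth = CloneTruth("c", [(4_900, 5_100)])
        report = segments.match_truth([], truth, m)
        assert len(report.undetectable) == 1
        assert report.undetectable.iloc[0]["n_markers"] == 1
        assert len(report.matches) == 0

    def test_detected_planting_matches_marker_hull(self, toy_config):
        from ctcnt import simulate
        from ctcnt.types import CloneTruth

        m = simulate.generate_marker_map(toy_config)
        truth = CloneTruth("c", [(50_000, 90_000)])
        track = simulate._genotype_from_segments(
            m, truth.segments, "c", np.random.default_rng(0), 0.0
        )
        called = segments.call_segments(track, m)
        report = segments.match_truth(called, truth, m)
        row = report.matches.iloc[0]
        assert row["detected"] and row["exact_hull"]
        assert row["start_offset"] == 0 and row["end_offset"] == 0
        idx = m.site_indices_in(50_000, 90_000)
        assert row["hull_start"] == m.positions[idx[0]]
        assert row["hull_end"] == m.positions[idx[-1]]

    def test_overlapping_plantings_merge_into_one_component(self):
        from ctcnt.types import CloneTruth

        m = make_map(np.arange(100, 20_000, 100), genome_length=30_000)
        truth = CloneTruth("c", [(1_000, 6_000), (5_000, 11_000)])
        track_states = np.array(
            [1 if 1_000 <= p <= 11_000 else 0 for p in m.positions], dtype=np.int8
        )
        called = segments.call_segments(GenotypeTrack("c", track_states), m)
        report = segments.match_truth(called, truth, m)
        assert len(report.matches) == 1
        assert report.matches.iloc[0]["exact_hull"]
        assert report.false_calls == []
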