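"""The directional scan, iterative thresholding and stringent selection."""

import numpy as np
import pytest

from ctcfloops import (
    ThresholdSchedule,
    apply_peak_threshold,
    loop_length,
    predict_loops,
    scan_chromosome,
    select_top_loops,
)


def episode_oracle(anchor_spec):
    """Brute-force reference for the single-pass scan.

    Splits the (position-ordered) strand sequence into maximal episodes: a +
    anchor that follows any - anchor starts a new episode.  Every ordered
    (+, -) pair within one episode is a loop.  Independent of the scan's
    list bookkeeping.
    """
    episodes, current, seen_minus = [], [], False
    for pos, strand in anchor_spec:
        if strand == "+" and seen_minus:
            episodes.append(current)
            current, seen_minus = [], False
        current.append((pos, strand))
        seen_minus = seen_minus or strand == "-"
    episodes.append(current)
    loops = set()
    for episode in episodes:
        pluses = [p for p, s in episode if s == "+"]
        minuses = [p for p, s in episode if s == "-"]
        for p in pluses:
            for m in minuses:
                if p < m:
                    loops.add((p, m))
    return loops


def scan_pairs(anchors):
    return {(l.start_anchor.position, l.end_anchor.position) for l in anchors}


class TestScanChromosome:
    def test_hand_traced_example(self, make_anchor):
        anchors = [
            make_anchor(100, "+"), make_anchor(200, "+"), make_anchor(300, "-"),
            make_anchor(400, "-"), make_anchor(500, "+"), make_anchor(600, "-"),
        ]
        loops = scan_chromosome(anchors)
        assert scan_pairs(loops) == {
            (100, 300), (100, 400), (200, 300), (200, 400), (500, 600)
        }
        assert len(loops) == 5

    def test_end_anchors_without_start_anchors_give_no_loops(self, make_anchor):
        assert scan_chromosome([make_anchor(100, "-"), make_anchor(200, "-")]) == []

    def test_unclosed_start_anchor_gives_no_loops(self, make_anchor):
        assert scan_chromosome([make_anchor(100, "+")]) == []

    def test_unsorted_input_is_an_error(self, make_anchor):
        with pytest.raises(ValueError, match="sorted"):
            scan_chromosome([make_anchor(500, "+"), make_anchor(100, "-")])

    def test_multi_chromosome_input_is_an_error(self, make_anchor):
        with pytest.raises(ValueError, match="chromosome"):
            scan_chromosome(
                [make_anchor(100, "+"), make_anchor(200, "-", chrom="chr2")]
            )

    def test_matches_episode_oracle_on_random_anchor_sets(self, make_anchor, rng):
        for _ in range(300):
            n = int(rng.integers(0, 51))
            positions = sorted(rng.choice(100_000, size=n, replace=False))
            spec = [(int(p) + 100, "+-"[int(rng.integers(2))]) for p in positions]
            anchors = [make_anchor(p, s) for p, s in spec]
            assert scan_pairs(scan_chromosome(anchors)) == episode_oracle(spec)

    def test_every_emitted_loop_is_convergent(self, make_anchor, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            positions = sorted(rng.choice(50_000, size=n, replace=False))
            anchors = [
                make_anchor(int(p) + 100, "+-"[int(rng.integers(2))]) for p in positions
            ]
            for loop in scan_chromosome(anchors):
                assert loop.start_anchor.strand == "+"
                assert loop.end_anchor.strand == "-"
                assert loop.start_anchor.position < loop.end_anchor.position


class TestPeakThreshold:
    def test_floor_of_fraction_removed(self, make_anchor):
        anchors = [
            make_anchor(1000 * i, "+", peak_score=10 * (i + 1)) for i in range(10)
        ]
        assert len(apply_peak_threshold(anchors, 0.3)) == 7

    def test_fraction_zero_is_identity(self, make_anchor):
        anchors = [make_anchor(100, "+"), make_anchor(900, "-")]
        assert apply_peak_threshold(anchors, 0.0) == anchors

    def test_tie_break_removes_lower_coordinate_first(self, make_anchor):
        # stable-sort oracle: sorting (score, chrom, start) keeps the later
        # coordinate when two peaks tie at the cutoff score
        tied_low = make_anchor(100, "+", peak_score=5)
        tied_high = make_anchor(5000, "-", peak_score=5)
        strong = make_anchor(9000, "-", peak_score=50)
        anchors = [tied_low, tied_high, strong]
        expected_removed = sorted(
            anchors, key=lambda a: (a.peak.score, a.chrom, a.peak.interval.start)
        )[:1]
        retained = apply_peak_threshold(anchors, 1 / 3)
        assert retained == [tied_high, strong]
        assert expected_removed == [tied_low]

    def test_explicit_peak_universe_counts_motifless_peaks(self, make_anchor):
        from ctcfloops import GenomicInterval, Peak

        anchors = [make_anchor(100, "+", peak_score=500)]
        noise = [
            Peak(GenomicInterval("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 200), 1.0)
            for i in range(9)
        ]
        universe = noise + [anchors[0].peak]
        # 10 peaks total; removing 50% strips the 5 weakest (all noise)
        assert apply_peak_threshold(anchors, 0.5, peaks=universe) == anchors


class TestPredictLoops:
    def test_nested_loop_recovered_by_schedule(self, make_anchor):
        anchors = [
            make_anchor(100, "+", peak_score=10),
            make_anchor(300, "-", peak_score=5),
            make_anchor(400, "+", peak_score=5),
            make_anchor(700, "-", peak_score=10),
        ]
        base = predict_loops(anchors, ThresholdSchedule(final=0.0))
        assert scan_pairs(base) == {(100, 300), (400, 700)}
        merged = predict_loops(anchors)
        assert scan_pairs(merged) == {(100, 300), (400, 700), (100, 700)}
        by_pair = {
            (l.start_anchor.position, l.end_anchor.position): l.discovery_threshold
            for l in merged
        }
        assert by_pair[(100, 300)] == 0.0 and by_pair[(400, 700)] == 0.0
        assert by_pair[(100, 700)] > 0.0

    def test_final_zero_equals_single_scan(self, make_anchor):
        anchors = [make_anchor(100, "+"), make_anchor(900, "-"), make_anchor(2000, "+")]
        single = scan_chromosome(sorted(anchors, key=lambda a: a.position))
        assert scan_pairs(predict_loops(anchors, ThresholdSchedule(final=0.0))) == scan_pairs(single)

    def test_uniform_scores_merge_to_threshold_zero_set(self, make_anchor, rng):
        # all peaks in one score class: thresholding removes prefixes by the
        # coordinate tie-break; brute-forcing every iteration shows the merged
        # set only ever adds pairs, never loses the threshold-0 ones
        positions = sorted(rng.choice(50_000, size=20, replace=False))
        anchors = [
            make_anchor(int(p) + 100, "+-"[int(rng.integers(2))], peak_score=7)
            for p in positions
        ]
        merged = scan_pairs(predict_loops(anchors))
        base = scan_pairs(predict_loops(anchors, ThresholdSchedule(final=0.0)))
        assert base <= merged

    def test_merged_set_at_least_threshold_zero_size(self, make_anchor, rng):
        for _ in range(20):
            positions = sorted(rng.choice(100_000, size=30, replace=False))
            anchors = [
                make_anchor(
                    int(p) + 100,
                    "+-"[int(rng.integers(2))],
                    peak_score=float(rng.integers(1, 1000)),
                )
                for p in positions
            ]
            merged = predict_loops(anchors)
            base = predict_loops(anchors, ThresholdSchedule(final=0.0))
            assert len(merged) >= len(base)
            assert scan_pairs(base) <= scan_pairs(merged)

    def test_empty_anchor_set_gives_empty_loops(self):
        assert predict_loops([]) == []

    def test_score_mode_uses_score_cutoffs(self, make_anchor):
        anchors = [
            make_anchor(100, "+", peak_score=10),
            make_anchor(300, "-", peak_score=5),
            make_anchor(400, "+", peak_score=5),
            make_anchor(700, "-", peak_score=10),
        ]
        peaks = [a.peak for a in anchors]
        merged = predict_loops(
            anchors, ThresholdSchedule(mode="score"), peaks=peaks
        )
        assert (100, 700) in scan_pairs(merged)


class TestSelectTopLoops:
    def test_distinct_scores_top_five_of_hundred(self, make_anchor):
        anchors = [
            (make_anchor(10_000 * i, "+", peak_score=i + 1),
             make_anchor(10_000 * i + 2000, "-", peak_score=i + 1))
            for i in range(100)
        ]
        loops = [
            l for s, e in anchors for l in scan_chromosome([s, e])
        ]
        top = select_top_loops(loops, top_fraction=0.05)
        assert len(top) == 5
        assert sorted(l.score for l in top) == [96, 97, 98, 99, 100]

    def test_length_gate_applied_before_ranking(self, make_anchor):
        giant = scan_chromosome(
            [make_anchor(0, "+", peak_score=1e6),
             make_anchor(1_300_000, "-", peak_score=1e6)]
        )
        small = scan_chromosome(
            [make_anchor(2_000_000, "+", peak_score=10),
             make_anchor(2_050_000, "-", peak_score=10)]
        )
        top = select_top_loops(giant + small, top_fraction=0.5)
        assert scan_pairs(top) == {(2_000_000, 2_050_000)}

    def test_all_tied_scores_keep_genomically_first(self, make_anchor):
        loops = [
            l
            for i in range(10)
            for l in scan_chromosome(
                [make_anchor(50_000 * i, "+", peak_score=42),
                 make_anchor(50_000 * i + 10_000, "-", peak_score=42)]
            )
        ]
        top = select_top_loops(loops, top_fraction=0.1)
        assert len(top) == 1
        assert top[0].start_anchor.position == 0

    def test_loop_length_uses_inner_motif_edges(self, make_anchor):
        (loop,) = scan_chromosome(
            [make_anchor(1000, "+"), make_anchor(5000, "-")]
        )
        assert loop_length(loop) == 5000 - (1000 + 19)


class TestScheduleValidation:
    def test_threshold_sequence(self):
        assert ThresholdSchedule().thresholds() == pytest.approx(
            [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        )

    @pytest.mark.parametrize("inc,final", [(-0.1, 0.5), (0.7, 0.6), (0.1, 1.0)])
    def test_invalid_schedules_rejected(self, inc, final):
        with pytest.raises(ValueError):
            ThresholdSchedule(increment=inc, final=final)
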