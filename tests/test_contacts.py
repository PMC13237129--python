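"""Touch detection, gap-tolerant assembly and classification."""

import numpy as np
import pytest

from scanstop.contacts import (AnalysisParameters, Contact, Touch,
                               assemble_contacts, classify_contacts,
                               detect_touches, targets_visited)
from scanstop.geometry import Polygon

from conftest import brute_force_contacts, square_track

PARAMS = AnalysisParameters()


def touch_list(frames, tcell_id=0, target_id=1, area=10.0):
    return [Touch(f, tcell_id, target_id, area, 0.5) for f in frames]


def contact(tcell_id, target_id, frames, area=10.0):
    return Contact(tcell_id, target_id, tuple(frames),
                   cumulative_intersection_area=area)


class TestDetectTouches:
    def _one_pair(self, t_center, half, trg_center, trg_half,
                  params=PARAMS, n_frames=1):
        tc = square_track(0, "tcell", range(n_frames),
                          [t_center] * n_frames, half=half)
        trg = square_track(10, "target", range(n_frames),
                           [trg_center] * n_frames, half=trg_half)
        return detect_touches([tc], [trg], params)

    def test_full_containment_fraction_one(self):
        touches = self._one_pair((50, 50), 5, (50, 50), 20)
        assert len(touches) == 1
        assert touches[0].overlap_fraction == pytest.approx(1.0, rel=1e-6)

    def test_below_ten_percent_no_touch(self):
        # T square side 10 (area 100); target overlapping a 9.9 x 1 strip
        # would be under threshold: use offset giving ~5% overlap
        touches = self._one_pair((0, 0), 5, (9.5, 0), 5)
        assert touches == []

    def test_exactly_ten_percent_is_touch(self):
        """'At least 10%' is inclusive: build an overlap of exactly 10% of
        the upscaled T-cell area."""
        params = AnalysisParameters(upscale_factor=1.0)
        # T square side 10 area 100; target overlaps a 1 x 10 strip = 10
        tc = square_track(0, "tcell", [0], [(0.0, 0.0)], half=5)
        trg = square_track(10, "target", [0], [(9.0, 0.0)], half=5)
        touches = detect_touches([tc], [trg], params)
        assert len(touches) == 1
        assert touches[0].overlap_fraction == pytest.approx(0.10)

    def test_upscaled_area_is_denominator(self):
        """With upscaling on, the same 10-um^2 overlap falls just below the
        threshold because the denominator grows by 1.002^2."""
        strict = AnalysisParameters(upscale_factor=1.0)
        tc = square_track(0, "tcell", [0], [(0.0, 0.0)], half=5)
        # upscaled square reaches to 5.01, overlap strip widens too; compute
        # via the emitted fraction instead of geometry by hand
        trg = square_track(10, "target", [0], [(9.0, 0.0)], half=5)
        t_plain = detect_touches([tc], [trg], strict)[0]
        t_up = detect_touches([tc], [trg], AnalysisParameters())
        # upscale widens the intersection strip from 1.0 to ~1.01 while the
        # area grows by 1.004: fraction stays >= 10% -> still a touch
        assert t_plain.overlap_fraction == pytest.approx(0.10)
        assert len(t_up) == 1
        assert t_up[0].intersection_area > t_plain.intersection_area

    def test_multiple_targets_same_frame(self):
        tc = square_track(0, "tcell", [0], [(0.0, 0.0)], half=5)
        left = square_track(10, "target", [0], [(-8.0, 0.0)], half=5)
        right = square_track(11, "target", [0], [(8.0, 0.0)], half=5)
        touches = detect_touches([tc], [left, right], PARAMS)
        assert {t.target_id for t in touches} == {10, 11}

    def test_missing_observation_skipped(self):
        tc = square_track(0, "tcell", [0, 2], [(50, 50), (50, 50)], half=5)
        trg = square_track(10, "target", [0, 1, 2], [(50, 50)] * 3, half=20)
        touches = detect_touches([tc], [trg], PARAMS)
        assert [t.frame for t in touches] == [0, 2]

    def test_threshold_monotonicity(self, rng):
        tc = square_track(0, "tcell", range(10),
                          [tuple(rng.uniform(0, 60, 2)) for _ in range(10)],
                          half=5)
        trg = square_track(10, "target", range(10), [(30, 30)] * 10,
                           half=15)
        counts = [
            len(detect_touches([tc], [trg],
                               AnalysisParameters(overlap_fraction_min=f)))
            for f in (0.05, 0.10, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAssembleContacts:
    def test_consecutive_frames_one_contact(self):
        (c,) = assemble_contacts(touch_list([3, 4, 5]), PARAMS)
        assert c.touch_frames == (3, 4, 5)
        assert c.first_frame == 3 and c.last_frame == 5
        assert c.duration_frames == 3

    def test_gap_of_five_tolerated(self):
        (c,) = assemble_contacts(touch_list([3, 9]), PARAMS)
        assert c.touch_frames == (3, 9)

    def test_gap_of_six_splits(self):
        contacts = assemble_contacts(touch_list([3, 10]), PARAMS)
        assert len(contacts) == 2

    def test_separate_pairs_never_merge(self):
        touches = touch_list([1, 2], target_id=1) + \
            touch_list([2, 3], target_id=2)
        contacts = assemble_contacts(touches, PARAMS)
        assert len(contacts) == 2
        assert {c.target_id for c in contacts} == {1, 2}

    def test_touch_conservation(self, rng):
        for _ in range(20):
            frames = sorted(rng.choice(40, size=rng.integers(1, 20),
                                       replace=False))
            contacts = assemble_contacts(touch_list(frames), PARAMS)
            assert sum(c.n_touches for c in contacts) == len(frames)

    @pytest.mark.parametrize("max_gap", [0, 1, 5])
    def test_matches_union_find_oracle(self, rng, max_gap):
        params = AnalysisParameters(max_gap_frames=max_gap)
        for _ in range(60):
            frames = sorted(rng.choice(30, size=rng.integers(1, 15),
                                       replace=False))
            got = [list(c.touch_frames)
                   for c in assemble_contacts(touch_list(frames), params)]
            assert sorted(got) == brute_force_contacts(set(frames), max_gap)

    def test_gap_monotonicity(self, rng):
        frames = sorted(rng.choice(60, size=25, replace=False))
        counts = [
            len(assemble_contacts(
                touch_list(frames),
                AnalysisParameters(max_gap_frames=g)))
            for g in range(8)
        ]
        assert counts == sorted(counts, reverse=True)


class TestClassifyContacts:
    def test_contact_reaching_final_frame_is_stable(self):
        (c,) = classify_contacts([contact(0, 1, [50, 90])], PARAMS)
        assert c.classification == "stable"

    def test_contact_within_gap_of_end_is_stable(self):
        (c,) = classify_contacts([contact(0, 1, [50, 85])], PARAMS)
        assert c.classification == "stable"

    def test_contact_ending_early_is_transient(self):
        (c,) = classify_contacts([contact(0, 1, [30, 60])], PARAMS)
        assert c.classification == "transient"

    def test_longest_end_reaching_contact_wins(self):
        contacts = [contact(0, 1, list(range(51, 91))),   # duration 40
                    contact(0, 2, list(range(66, 91)))]   # duration 25
        out = {c.target_id: c.classification
               for c in classify_contacts(contacts, PARAMS)}
        assert out == {1: "stable", 2: "transient"}

    def test_duration_tie_broken_by_area_then_id(self):
        a = contact(0, 5, [80, 90], area=50.0)
        b = contact(0, 3, [80, 90], area=10.0)
        out = {c.target_id: c.classification
               for c in classify_contacts([a, b], PARAMS)}
        assert out == {5: "stable", 3: "transient"}
        c1 = contact(0, 5, [80, 90], area=10.0)
        c2 = contact(0, 3, [80, 90], area=10.0)
        out = {c.target_id: c.classification
               for c in classify_contacts([c1, c2], PARAMS)}
        assert out == {3: "stable", 5: "transient"}

    def test_at_most_one_stable_per_cell(self, rng):
        for _ in range(30):
            contacts = []
            for tid in range(1, int(rng.integers(2, 6))):
                start = int(rng.integers(0, 89))
                end = int(rng.integers(start, 91))
                contacts.append(contact(0, tid, [start, end]
                                        if end > start else [start]))
            out = classify_contacts(contacts, PARAMS)
            stable = [c for c in out if c.classification == "stable"]
            assert len(stable) <= 1
            for c in stable:
                assert PARAMS.final_frame - c.last_frame <= \
                    PARAMS.max_gap_frames

    def test_truncated_track_flagged(self):
        out = classify_contacts([contact(0, 1, [10, 20])], PARAMS,
                                tcell_last_frames={0: 25})
        assert out[0].track_truncated
        out = classify_contacts([contact(0, 1, [10, 90])], PARAMS,
                                tcell_last_frames={0: 90})
        assert not out[0].track_truncated


class TestTargetsVisited:
    def test_distinct_count(self):
        contacts = [contact(0, 7, [1]), contact(0, 7, [20]),
                    contact(0, 9, [5])]
        assert targets_visited(contacts, 0) == 2

    def test_no_contacts(self):
        assert targets_visited([], 0) == 0

    def test_regardless_of_classification(self):
        contacts = classify_contacts(
            [contact(0, 4, [1]), contact(0, 4, [20]),
             contact(0, 4, [40]), contact(0, 4, [60, 90])], PARAMS)
        assert targets_visited(contacts, 0) == 1
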