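"""Stopping speed, density normalization and group summaries."""

import numpy as np
import pytest

from scanstop.contacts import AnalysisParameters, Contact
from scanstop.metrics import (density_factors, stopping_speed,
                              summarize_group)

from conftest import make_track

PARAMS = AnalysisParameters()


def stable_contact(first, last, tcell_id=0, target_id=1):
    return Contact(tcell_id, target_id, (first, last),
                   cumulative_intersection_area=10.0,
                   classification="stable")


class TestStoppingSpeed:
    def test_advance_then_freeze_closed_form(self):
        """2 um/frame for 5 frames after first touch, then frozen:
        max displacement 10 um reached after 300 s -> 1/30 um/s."""
        frames = list(range(60, 91))
        xs = [min(2.0 * (f - 60), 10.0) for f in frames]
        track = make_track(0, "tcell", frames, [(x, 0.0) for x in xs])
        prof = stopping_speed(stable_contact(60, 90), track, PARAMS)
        assert prof.max_displacement == pytest.approx(10.0)
        assert prof.time_to_max == pytest.approx(300.0)
        assert prof.stopping_speed == pytest.approx(10.0 / 300.0)
        assert not prof.flagged_instantaneous

    def test_stationary_from_touch_zero(self):
        frames = list(range(60, 91))
        track = make_track(0, "tcell", frames, [(5.0, 5.0)] * len(frames))
        prof = stopping_speed(stable_contact(60, 90), track, PARAMS)
        assert prof.max_displacement == 0.0
        assert prof.stopping_speed == 0.0
        assert prof.flagged_instantaneous

    def test_earliest_frame_attaining_max_used(self):
        # out to 8 um at frame 62, return, out to 8 um again at frame 70
        frames = list(range(60, 91))
        xs = []
        for f in frames:
            if f == 62 or f == 70:
                xs.append(8.0)
            elif f < 70:
                xs.append(4.0)
            else:
                xs.append(0.0)
        track = make_track(0, "tcell", frames, [(x, 0.0) for x in xs])
        prof = stopping_speed(stable_contact(60, 90), track, PARAMS)
        assert prof.time_to_max == pytest.approx(2 * 60.0)

    def test_missing_first_touch_observation_flagged(self):
        frames = [62, 63, 90]
        track = make_track(0, "tcell", frames, [(0, 0), (3, 0), (3, 0)])
        prof = stopping_speed(stable_contact(60, 90), track, PARAMS)
        assert prof.flagged_missing_first_touch
        assert prof.max_displacement == pytest.approx(3.0)

    def test_requires_stable_contact(self):
        track = make_track(0, "tcell", [0, 1], [(0, 0), (1, 1)])
        c = Contact(0, 1, (0, 1), 1.0, classification="transient")
        with pytest.raises(ValueError):
            stopping_speed(c, track, PARAMS)

    def test_nonnegative_on_random_walks(self, rng):
        frames = list(range(40, 91))
        for _ in range(10):
            pts = np.cumsum(rng.normal(0, 2, (len(frames), 2)), axis=0)
            track = make_track(0, "tcell", frames, pts)
            prof = stopping_speed(stable_contact(40, 90), track, PARAMS)
            assert prof.stopping_speed >= 0.0
            assert prof.max_displacement == pytest.approx(
                max(d for _, d in prof.displacement_series))


class TestDensityFactors:
    def test_single_field_is_unity(self):
        assert density_factors([12]) == [1.0]

    def test_two_field_example(self):
        assert density_factors([10, 20]) == pytest.approx([2 / 3, 4 / 3])

    def test_group_mean_is_one(self, rng):
        counts = rng.integers(1, 50, size=12)
        assert np.mean(density_factors(counts)) == pytest.approx(
            1.0, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            density_factors([0, 0])


class TestSummarizeField:
    def _fit(self, seed=3):
        from scanstop.assay import ScanStopAssay
        from scanstop.simulate import SimulationConfig
        return ScanStopAssay.from_simulation(
            SimulationConfig(seed=seed, n_tcells=30)).fit()

    def test_percentage_arithmetic(self):
        res = self._fit()
        fs = res.field_summary
        assert fs.raw_stable_percent == pytest.approx(
            100.0 * fs.n_stable / fs.n_tcells_analyzed)
        assert fs.normalized_stable_percent == pytest.approx(
            fs.raw_stable_percent / fs.density_factor)

    def test_percentage_conservation(self):
        """Stable cells + transient-only cells + no-contact cells partition
        the analyzed cells."""
        res = self._fit(seed=11)
        kept = set(res.filter_report.kept)
        stable = {c.tcell_id for c in res.contacts
                  if c.classification == "stable"}
        transient_only = {c.tcell_id for c in res.contacts
                          if c.classification == "transient"} - stable
        none = kept - stable - transient_only
        assert len(stable) + len(transient_only) + len(none) == \
            res.field_summary.n_tcells_analyzed

    def test_zero_analyzed_reported_missing(self):
        from scanstop.assay import ScanStopAssay
        from scanstop.io import FieldDataset, FieldMetadata
        # all-drifter field: every track ballistic
        tracks = tuple(
            make_track(i, "tcell", range(10),
                       [(5.0 * f, float(i)) for f in range(10)])
            for i in range(4)
        )
        ds = FieldDataset(FieldMetadata(n_frames=10), tracks, ())
        res = ScanStopAssay(ds, AnalysisParameters(final_frame=9)).fit()
        assert res.field_summary.n_tcells_analyzed == 0
        assert res.field_summary.raw_stable_percent is None


class TestSummarizeGroup:
    def _fs(self, field_id, group_id, raw, n_targets):
        from scanstop.metrics import FieldSummary
        return FieldSummary(
            field_id=field_id, group_id=group_id, n_tcells_total=50,
            n_tcells_analyzed=50, n_stable=int(raw / 2),
            n_transient_cells=10, n_transient_contacts=12,
            raw_stable_percent=raw, raw_transient_percent=20.0,
            n_targets_in_field=n_targets, density_factor=1.0,
            normalized_stable_percent=raw, mean_targets_visited=1.0,
            mean_stable_contacts=0.1, mean_stopping_speed=0.03,
            total_distance_um=(500.0, 50.0),
            euclidean_distance_um=(100.0, 20.0),
            mean_speed_um_s=(0.1, 0.02), persistence=(0.2, 0.05))

    def test_single_field_mean_is_value_sd_zero(self):
        table = summarize_group([self._fs("f0", "g", 10.0, 15)])
        row = table.iloc[0]
        assert row.raw_stable_percent_mean == pytest.approx(10.0)
        assert row.raw_stable_percent_sd == 0.0
        assert row.n_fields == 1

    def test_sample_sd(self):
        table = summarize_group([self._fs("f0", "g", 8.0, 15),
                                 self._fs("f1", "g", 12.0, 15)])
        row = table.iloc[0]
        assert row.raw_stable_percent_mean == pytest.approx(10.0)
        assert row.raw_stable_percent_sd == pytest.approx(
            np.std([8, 12], ddof=1))

    def test_equal_densities_leave_percentages_unchanged(self):
        table = summarize_group([self._fs("f0", "g", 8.0, 15),
                                 self._fs("f1", "g", 12.0, 15)])
        row = table.iloc[0]
        assert row.normalized_stable_percent_mean == pytest.approx(
            row.raw_stable_percent_mean)

    def test_density_normalization_applied(self):
        table = summarize_group([self._fs("f0", "g", 9.0, 10),
                                 self._fs("f1", "g", 12.0, 20)])
        row = table.iloc[0]
        expected = np.mean([9.0 / (2 / 3), 12.0 / (4 / 3)])
        assert row.normalized_stable_percent_mean == pytest.approx(expected)

    def test_field_order_invariance(self):
        fields = [self._fs(f"f{i}", "g", 5.0 + i, 10 + i) for i in range(4)]
        t1 = summarize_group(fields)
        t2 = summarize_group(fields[::-1])
        assert t1.equals(t2)
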