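"""Stimulus rendering: bar apertures, temporal profiles, run assembly."""

import numpy as np
import pytest
from scipy.integrate import quad

import stprf
from stprf.design import (
    BarGeometry,
    TemporalCondition,
    build_bar_aperture,
    build_temporal_profile,
    default_conditions,
    spatiotemporal_sequence,
    toonotopy_sequence,
)
from stprf.exceptions import (
    InvalidDesignError,
    ScheduleOverflowError,
)


def band_disk_area(center, width, radius):
    """Analytic area of {|x - center| <= width/2} within a disk."""
    lo = max(center - width / 2, -radius)
    hi = min(center + width / 2, radius)
    if lo >= hi:
        return 0.0
    return quad(lambda x: 2.0 * np.sqrt(radius**2 - x**2), lo, hi)[0]


class TestBarAperture:
    @pytest.mark.parametrize("angle,step", [(0.0, 0), (0.0, 4), (45.0, 4),
                                            (90.0, 8), (135.0, 2)])
    def test_pixel_count_matches_analytic_band_area(self, angle, step):
        geom = BarGeometry.spatiotemporal()
        ap = build_bar_aperture(geom, angle, step)
        area_px = ap.sum() * geom.pixel_size_deg**2
        area_true = band_disk_area(geom.bar_centers_deg()[step],
                                   geom.bar_width_deg, geom.field_radius_deg)
        # pixel-center counting quantizes the band/disk boundary; allow
        # roughly half a pixel of slack along the region's perimeter
        assert area_px == pytest.approx(area_true, rel=0.12)

    def test_center_bar_fraction_near_width_over_diameter(self):
        geom = BarGeometry.spatiotemporal()
        ap = build_bar_aperture(geom, 0.0, 4)
        frac = ap.sum() / ap.size
        # one pixel column of quantization plus disk clipping ~= 9%
        assert frac == pytest.approx(geom.bar_width_deg / geom.diameter_deg,
                                     rel=0.1)

    def test_adjacent_steps_spacing_and_overlap(self):
        geom = BarGeometry.spatiotemporal()
        centers = geom.bar_centers_deg()
        assert np.allclose(np.diff(centers), 2.625)
        assert geom.bar_width_deg - geom.step_deg == pytest.approx(0.375)

    def test_binary_and_confined_to_field(self):
        geom = BarGeometry.spatiotemporal()
        X, Y = geom.pixel_grid()
        outside = X**2 + Y**2 > geom.field_radius_deg**2
        for angle in geom.angles_deg:
            for step in range(geom.n_steps):
                ap = build_bar_aperture(geom, angle, step)
                assert set(np.unique(ap)) <= {0, 1}
                assert not ap[outside].any()

    def test_invalid_step_or_angle_rejected(self):
        geom = BarGeometry.spatiotemporal()
        with pytest.raises(InvalidDesignError):
            build_bar_aperture(geom, 0.0, 9)
        with pytest.raises(InvalidDesignError):
            build_bar_aperture(geom, 30.0, 0)

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(InvalidDesignError):
            BarGeometry(bar_width_deg=4.0)  # does not tile 24 deg in 9 steps


class TestTemporalProfiles:
    def test_condition_table_structure(self):
        conds = default_conditions()
        assert all(conds[i].on_ms == 133.0 for i in (1, 2, 3))
        assert [conds[i].isi_ms for i in (1, 2, 3)] == [33.0, 200.0, 867.0]
        assert all(conds[i].isi_ms == 133.0 for i in (4, 5, 6))
        assert [conds[i].on_ms for i in (4, 5, 6)] == [33.0, 200.0, 867.0]
        assert [conds[i].n_images for i in (1, 7, 8)] == [30, 15, 5]

    @pytest.mark.parametrize("cid,n_epochs", [(1, 30), (2, 15), (3, 5),
                                              (4, 30), (7, 15), (8, 5)])
    def test_epoch_counts(self, cid, n_epochs):
        prof = build_temporal_profile(default_conditions()[cid])
        onsets = np.flatnonzero(np.diff(prof.astype(int), prepend=0) == 1)
        assert len(onsets) == n_epochs

    def test_continuous_condition_fully_on(self):
        prof = build_temporal_profile(default_conditions()[9])
        assert len(prof) == 500 and prof.all()

    @pytest.mark.parametrize("cid", [1, 7, 8])
    def test_matched_total_on_time_conditions(self, cid):
        prof = build_temporal_profile(default_conditions()[cid])
        assert prof.sum() * 10.0 == pytest.approx(4000.0, abs=120.0)

    def test_on_time_matches_schedule_within_a_frame(self):
        for cond in default_conditions().values():
            prof = build_temporal_profile(cond)
            assert abs(prof.sum() * 10.0 - cond.n_images * cond.on_ms) <= 15.0

    def test_overflow_rejected(self):
        with pytest.raises(ScheduleOverflowError):
            TemporalCondition(1, on_ms=600.0, isi_ms=0.0, n_images=10,
                              slot_ms=1000.0)


class TestRunAssembly:
    def test_frames_are_aperture_and_profile(self, mini_seq):
        slot = mini_seq.slots[3]
        a, b = slot["start"], slot["start"] + slot["n_frames"]
        frames = mini_seq.frames(a, b)
        prof = mini_seq.profiles[slot["profile"]]
        expected = prof[:, None, None] * mini_seq.apertures[slot["aperture"]]
        assert np.array_equal(frames, expected)

    def test_stimulated_duration_and_binary_values(self):
        seq = spatiotemporal_sequence(n_runs=1, seed=0)
        assert seq.n_frames == 4 * 9 * 500          # 180 s at 10 ms
        sample = seq.frames(0, 700)
        assert set(np.unique(sample)) <= {0, 1}

    def test_counterbalance_each_condition_once_per_location(self):
        seq = spatiotemporal_sequence(n_runs=9, seed=4)
        counts = {}
        for slot in seq.slots:
            key = (slot["aperture"], slot["condition"])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 36 * 9
        assert set(counts.values()) == {1}

    def test_all_off_condition_gives_zero_sequence(self, mini_geometry):
        off = {1: TemporalCondition(1, on_ms=0.0, isi_ms=0.0, n_images=1,
                                    slot_ms=1000.0)}
        schedules = stprf.counterbalanced_schedules(mini_geometry, 1, seed=0)
        rows = tuple(tuple(1 for _ in r) for r in schedules[0].conditions)
        from stprf.design import RunSchedule, _assemble

        seq = _assemble(mini_geometry,
                        [RunSchedule(mini_geometry.angles_deg, rows)],
                        off, 10.0, "mini")
        assert not seq.frames().any()

    def test_rendering_is_deterministic(self):
        a = spatiotemporal_sequence(n_runs=2, seed=5)
        b = spatiotemporal_sequence(n_runs=2, seed=5)
        assert np.array_equal(a.slots, b.slots)
        assert np.array_equal(a.apertures, b.apertures)
        c = spatiotemporal_sequence(n_runs=2, seed=6)
        assert not np.array_equal(a.slots, c.slots)

    def test_subset_runs_preserves_drive(self, mini_seq, mini_geometry):
        rf = np.ones((mini_geometry.grid_px,) * 2)
        full = mini_seq.drive(rf)
        sub = mini_seq.subset_runs([1])
        sl = mini_seq.run_slices()[1]
        assert np.allclose(sub.drive(rf), full[sl])


class TestToonotopy:
    def test_sweep_and_run_length(self):
        seq = toonotopy_sequence(n_runs=1)
        # 4 angles x 12 steps x 2 s
        assert seq.n_frames == 4 * 12 * 200
        assert seq.geometry.n_steps == 12
        assert seq.geometry.bar_width_deg - seq.geometry.step_deg == \
            pytest.approx(0.27)

    def test_refresh_interval_125_ms(self):
        seq = toonotopy_sequence(n_runs=1)
        prof = seq.profiles[0]
        onsets = np.flatnonzero(np.diff(prof.astype(int), prepend=0) == 1)
        assert len(onsets) == 16                     # 8 Hz over 2 s
        assert np.allclose(np.diff(onsets), 12.5, atol=0.5)

    def test_continuous_rendering_option(self):
        seq = toonotopy_sequence(n_runs=1, refresh_transients=False)
        assert seq.profiles[0].all()
        sample = seq.frames(0, 300)
        assert set(np.unique(sample)) <= {0, 1}
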