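"""Bubble segmentation, shape metrics, tracking and classification."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import ellipe

from bubblekin import segmentation as seg


def _disk(shape, cx, cy, r, value=0.01):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2) * value


def _ellipse(shape, cx, cy, a, b, value=0.01):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2) <= 1.0) * value


class TestSegmentFrame:
    def test_disk_circularity_near_one(self):
        _, m = seg.segment_frame(_disk((512, 512), 256, 256, 100), 1.0)
        assert len(m) == 1
        assert m[0].circularity == pytest.approx(1.0, abs=0.02)

    def test_ellipse_circularity_matches_elliptic_integral(self):
        _, m = seg.segment_frame(_ellipse((512, 512), 256, 256, 200, 100), 1.0)
        a, b = 200.0, 100.0
        perimeter = 4 * a * ellipe(1 - (b / a) ** 2)
        oracle = 4 * np.pi * (np.pi * a * b) / perimeter**2
        assert m[0].circularity == pytest.approx(oracle, abs=0.02)

    def test_circularity_decreases_with_aspect_ratio(self):
        shapes = [
            _disk((512, 512), 256, 256, 100),
            _ellipse((512, 512), 256, 256, 200, 100),
            _ellipse((512, 512), 256, 256, 240, 60),
        ]
        circs = [seg.segment_frame(s, 1.0)[1][0].circularity for s in shapes]
        assert circs[0] > circs[1] > circs[2]
        assert all(c <= 1.05 for c in circs)

    def test_empty_map_gives_no_components(self):
        labels, m = seg.segment_frame(np.zeros((32, 32)), 25.0)
        assert m == []
        assert labels.max() == 0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            seg.segment_frame(np.full((4, 4), -0.1), 25.0)

    def test_area_uses_pixel_size(self):
        _, m = seg.segment_frame(_disk((64, 64), 32, 32, 10), 25.0)
        assert m[0].area_um2 == pytest.approx(np.pi * (10 * 25.0) ** 2, rel=0.05)


class TestTracking:
    def _grow_stack(self, n=12, shape=(64, 64)):
        return [
            _disk(shape, 32, 32, 6 + 0.5 * i) for i in range(n)
        ], np.arange(n) / 3.0

    def test_single_growing_disk_is_one_track(self):
        frames, times = self._grow_stack()
        labels, meas = seg.segment_stack(np.array(frames), times, 25.0)
        tracks = seg.track_bubbles(labels, meas, times, pixel_size_um=25.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == len(frames)
        assert tracks[0].status == "active"

    def test_upward_exit_marks_track_exited(self):
        shape = (64, 64)
        frames = [_disk(shape, 32, 40 - 6 * i, 8) for i in range(6)]
        # bubble centre moves up and finally leaves the frame
        frames.append(np.zeros(shape))
        times = np.arange(7) / 3.0
        labels, meas = seg.segment_stack(np.array(frames), times, 25.0)
        tracks = seg.track_bubbles(labels, meas, times, pixel_size_um=25.0)
        tr = tracks[0]
        assert tr.status == "exited"
        assert tr.exit_time == pytest.approx(times[5] + 1 / 3.0)
        assert tr.frozen_sum_dtau is not None

    def test_disappearance_away_from_top_is_anomaly(self):
        shape = (64, 64)
        frames = [_disk(shape, 32, 32, 8)] * 4 + [np.zeros(shape)]
        times = np.arange(5) / 3.0
        labels, meas = seg.segment_stack(np.array(frames), times, 25.0)
        tracks = seg.track_bubbles(labels, meas, times, pixel_size_um=25.0)
        assert tracks[0].status == "active"
        assert tracks[0].anomaly

    def test_merge_produces_successor_with_summed_area(self):
        shape = (64, 128)
        frames = []
        for i in range(8):
            r = 6 + 1.2 * i
            frames.append(_disk(shape, 30, 32, r) + _disk(shape, 58, 32, r))
        times = np.arange(8) / 3.0
        labels, meas = seg.segment_stack(np.array(frames), times, 25.0)
        tracks = seg.track_bubbles(labels, meas, times, pixel_size_um=25.0)
        merged = [t for t in tracks if t.status == "merged"]
        successors = [t for t in tracks if t.parents]
        assert len(merged) == 2
        assert len(successors) == 1
        succ = successors[0]
        # the successor's area is the two just-touching disks together
        r_merge = (6 + 1.2 * 7) * 25.0
        assert succ.measurements[0].area_um2 == pytest.approx(
            2 * np.pi * r_merge**2, rel=0.05)

    def test_track_areas_partition_total_area(self):
        frames, times = self._grow_stack()
        arr = np.array(frames)
        labels, meas = seg.segment_stack(arr, times, 25.0)
        tracks = seg.track_bubbles(labels, meas, times, pixel_size_um=25.0)
        for fi in range(len(frames)):
            total = sum(m.area_um2 for m in meas[fi])
            per_track = sum(
                m.area_um2
                for t in tracks
                for m in t.measurements
                if m.frame == fi
            )
            assert per_track == pytest.approx(total)


class TestClassification:
    def test_scenarios_classify_as_constructed(self, scenario_tracks):
        expected = {
            "diffusion": "unconstrained",
            "vessel": "vessel_confined",
            "alveolar": "alveolar_stepped",
        }
        for scen, want in expected.items():
            assert seg.classify_growth(scenario_tracks[scen]["main"]) == want

    def test_alveolar_steps_match_compartment_count(self, scenario_tracks):
        # four compartments leave three upward steps in the area curve
        main = scenario_tracks["alveolar"]["main"]
        assert seg.count_area_steps(main) == 3

    def test_short_track_rejected(self):
        tr = seg.BubbleTrack(track_id=0)
        with pytest.raises(ValueError, match="need >= 10"):
            seg.classify_growth(tr)


class TestGrowthExponent:
    def _track_from_areas(self, times, areas):
        tr = seg.BubbleTrack(track_id=0, birth_time=0.0)
        for i, (t, a) in enumerate(zip(times, areas)):
            tr.measurements.append(
                seg.BubbleMeasurement(1, i, t, a, 2 * np.sqrt(np.pi * a), 1.0,
                                      (0, 0), 0.01, 0.01, 10)
            )
        return tr

    def test_linear_area_gives_slope_one(self):
        t = np.linspace(0.5, 30, 60)
        tr = self._track_from_areas(t, 100.0 * t)
        slope, _ = seg.area_growth_exponent(tr, birth="track")
        assert slope == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_area_gives_slope_two(self):
        t = np.linspace(0.5, 30, 60)
        tr = self._track_from_areas(t, 5.0 * t**2)
        slope, _ = seg.area_growth_exponent(tr, birth="track")
        assert slope == pytest.approx(2.0, abs=1e-9)

    def test_diffusion_preset_slope_with_noise(self, scenario_tracks):
        main = scenario_tracks["diffusion"]["main"]
        slope, _ = seg.area_growth_exponent(main)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_radius_slope_is_half_of_area_slope(self, scenario_tracks):
        # A proportional to t implies dR/dt decaying as 1/sqrt(t)
        main = scenario_tracks["diffusion"]["main"]
        t_abo = main.times - seg.estimate_birth_time(main)
        good = t_abo > 0
        radius = np.sqrt(main.areas_um2 / np.pi)
        res = stats.linregress(np.log(t_abo[good]), np.log(radius[good]))
        assert res.slope == pytest.approx(0.5, abs=0.03)
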