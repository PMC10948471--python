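"""Track geometry: segment layout, staggers, curvature lookup, round-trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import paceopt as po
from paceopt.track import BASE_BEND_RADIUS, LANE_WIDTH


class TestBuild400:
    def test_lane1_segment_layout(self, track400):
        # standard track: 116 m bends of radius 36.5, 84 m straights,
        # starting on the first bend
        lengths = [seg.length for seg in track400.segments]
        curvatures = [seg.curvature for seg in track400.segments]
        assert lengths == [116.0, 84.0, 116.0, 84.0]
        assert curvatures == pytest.approx([1 / 36.5, 0.0, 1 / 36.5, 0.0])

    @pytest.mark.parametrize("lane", range(1, 10))
    def test_distance_conservation(self, lane):
        track = po.build_track(400, lane=lane)
        assert math.fsum(seg.length for seg in track.segments) == pytest.approx(
            400.0, abs=1e-9
        )

    def test_lane4_curvature_and_stagger(self):
        track = po.build_track(400, lane=4)
        assert track.bend_radius == pytest.approx(36.5 + 3 * 1.22)
        bends = [seg for seg in track.segments if seg.curvature > 0]
        assert bends[0].curvature == pytest.approx(1 / 40.16)
        # first bend shortened by the full stagger 2*pi*w*(n-1)
        full_bend = 116.0 + math.pi * 1.22 * 3
        assert bends[1].length == pytest.approx(full_bend)
        assert full_bend - bends[0].length == pytest.approx(2 * math.pi * 1.22 * 3)
        assert full_bend - bends[0].length == pytest.approx(22.996, abs=5e-4)

    def test_bend_curvature_decreases_with_lane(self):
        curvatures = [
            max(s.curvature for s in po.build_track(400, lane=n).segments)
            for n in range(1, 10)
        ]
        assert all(a > b for a, b in zip(curvatures, curvatures[1:]))

    @given(lane=st.integers(1, 9), width=st.floats(0.9, 1.5))
    @settings(max_examples=25, deadline=None)
    def test_all_lanes_cover_exactly_400(self, lane, width):
        track = po.build_track(400, lane=lane, lane_width=width)
        assert math.fsum(s.length for s in track.segments) == pytest.approx(
            400.0, abs=1e-9
        )
        assert track.bend_radius == pytest.approx(
            BASE_BEND_RADIUS + width * (lane - 1)
        )


class TestBuild1500:
    def test_total_distance_and_start(self, track1500):
        assert math.fsum(s.length for s in track1500.segments) == pytest.approx(
            1500.0, abs=1e-9
        )
        # curved start line: a short opening bend stub, then the back straight
        assert track1500.segments[0].curvature == pytest.approx(1 / 36.5)
        assert track1500.segments[0].length == pytest.approx(16.0)
        assert track1500.segments[1].curvature == 0.0

    def test_lane_restriction(self):
        with pytest.raises(ValueError, match="lane"):
            po.build_track(1500, lane=3)


class TestCurvatureAt:
    def test_400_values(self, track400):
        assert po.curvature_at(track400, 10.0) == pytest.approx(1 / 36.5)
        assert po.curvature_at(track400, 150.0) == 0.0

    def test_1500_opening(self, track1500):
        # 20 m lies in the opening back straight (after the 16 m stub)
        assert po.curvature_at(track1500, 20.0) == 0.0
        assert po.curvature_at(track1500, 5.0) == pytest.approx(1 / 36.5)

    def test_right_continuous_at_boundary(self, track400):
        # 116 m is the bend/straight junction: the straight's curvature wins
        assert po.curvature_at(track400, 116.0) == 0.0
        assert po.curvature_at(track400, 116.0 - 1e-9) == pytest.approx(1 / 36.5)

    @pytest.mark.parametrize("s", [-1.0, 400.001])
    def test_out_of_range(self, track400, s):
        with pytest.raises(ValueError):
            po.curvature_at(track400, s)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"event": 800},
            {"event": 400, "lane": 0},
            {"event": 400, "lane": 10},
            {"event": 400, "lane_width": -1.0},
            {"event": 400, "base_radius": 0.0},
        ],
    )
    def test_bad_inputs(self, kwargs):
        kwargs.setdefault("lane", 1)
        with pytest.raises(ValueError):
            po.build_track(**kwargs)

    def test_segment_invariants(self):
        with pytest.raises(ValueError):
            po.TrackSegment(-5.0, 0.0)
        with pytest.raises(ValueError):
            po.TrackSegment(5.0, -0.1)


def test_csv_round_trip(tmp_path, track400_lane4):
    path = tmp_path / "lane4.csv"
    track400_lane4.to_csv(path)
    back = po.TrackGeometry.from_csv(path)
    assert back.event_distance == track400_lane4.event_distance
    assert back.lane == track400_lane4.lane
    assert back.bend_radius == pytest.approx(track400_lane4.bend_radius)
    assert [s.length for s in back.segments] == pytest.approx(
        [s.length for s in track400_lane4.segments]
    )
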