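"""Bone-line polyline, cut frames and cross-section extraction."""

import numpy as np
import pytest

from mandicort import CTVolume
from mandicort.geometry import (compute_cut_frame, default_stations,
                                extract_cross_section, fit_bone_line, point_at,
                                project_station, tangent_at)


def straight_line(n=5):
    return fit_bone_line([(float(i * 3), 10.0) for i in range(n)])


class TestFitBoneLine:
    def test_collinear_points_length_equals_endpoint_distance(self):
        line = straight_line()
        assert line.total_length == pytest.approx(12.0)

    def test_arc_length_is_sum_of_segments(self):
        pts = [(0, 0), (3, 4), (6, 4), (6, 10), (10, 10)]
        line = fit_bone_line(pts)
        assert line.cum_lengths[-1] == pytest.approx(5 + 3 + 6 + 4)

    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_bone_line([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_coincident_consecutive_points_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            fit_bone_line([(0, 0), (0, 0), (2, 2), (3, 3), (4, 4)])


class TestCutFrame:
    def test_horizontal_line_has_vertical_normal(self):
        frame = compute_cut_frame(straight_line(), 0.5)
        np.testing.assert_allclose(np.abs(frame.normal), [0, 1], atol=1e-12)

    def test_tangent_and_normal_are_unit_and_orthogonal(self):
        pts = [(0, 0), (2, 5), (4, 6), (7, 3), (9, 0)]
        line = fit_bone_line(pts)
        for s in [0.0, 0.2, 0.5, 0.77, 1.0]:
            f = compute_cut_frame(line, s)
            assert np.linalg.norm(f.tangent) == pytest.approx(1.0)
            assert np.linalg.norm(f.normal) == pytest.approx(1.0)
            assert np.dot(f.tangent, f.normal) == pytest.approx(0.0, abs=1e-12)

    def test_station_zero_anchors_first_point(self):
        frame = compute_cut_frame(straight_line(), 0.0)
        np.testing.assert_allclose(frame.anchor, [0.0, 10.0])

    def test_station_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_cut_frame(straight_line(), 1.2)

    def test_straight_polyline_same_normal_at_both_endpoints(self):
        line = straight_line()
        f0 = compute_cut_frame(line, 0.0)
        f1 = compute_cut_frame(line, 1.0)
        np.testing.assert_allclose(f0.normal, f1.normal)

    def test_projection_recovers_on_line_points(self):
        line = straight_line()
        s = project_station(line, (6.0, 10.0))
        np.testing.assert_allclose(point_at(line, s), [6.0, 10.0])


class TestExtractCrossSection:
    def make_volume(self, rng=None):
        data = np.zeros((3, 20, 20))
        if rng is not None:
            data = rng.normal(size=(3, 20, 20))
        return CTVolume(data)

    def test_axis_aligned_frame_equals_direct_indexing(self, rng):
        """Oracle: a vertical cut on integer coordinates is just a column
        of the slice array."""
        vol = CTVolume(rng.normal(size=(3, 20, 20)))
        line = straight_line()  # horizontal, normal = (0, 1)
        frame = compute_cut_frame(line, 0.5, half_extent_px=5)
        # anchor (6, 10): samples rows 5..15 of column 6
        section = extract_cross_section(vol, 1, frame, depth_extent=1)
        sign = int(np.sign(frame.normal[1]))
        rows = 10 + sign * np.arange(-5, 6)
        np.testing.assert_allclose(section.image[:, 0], vol.data[1, rows, 6])

    def test_all_zero_volume_gives_all_zero_section(self):
        vol = self.make_volume()
        frame = compute_cut_frame(straight_line(), 0.5, half_extent_px=4)
        section = extract_cross_section(vol, 0, frame)
        np.testing.assert_array_equal(section.image, 0.0)

    def test_frame_outside_volume_warns_and_fills(self):
        vol = self.make_volume()
        line = fit_bone_line([(100 + i, 200.0) for i in range(5)])
        frame = compute_cut_frame(line, 0.5, half_extent_px=3)
        with pytest.warns(UserWarning, match="outside"):
            section = extract_cross_section(vol, 0, frame)
        np.testing.assert_array_equal(section.image, 0.0)

    def test_integer_translation_equivariance(self, rng):
        base = np.zeros((1, 30, 30))
        base[0, 8:14, 10:16] = rng.random((6, 6))
        vol = CTVolume(base)
        shifted = CTVolume(np.roll(base, (3, 2), axis=(1, 2)))
        pts = [(10.0 + i, 11.0) for i in range(5)]
        line = fit_bone_line(pts)
        line_shift = fit_bone_line([(x + 2, y + 3) for x, y in pts])
        f = compute_cut_frame(line, 0.5, half_extent_px=6)
        fs = compute_cut_frame(line_shift, 0.5, half_extent_px=6)
        a = extract_cross_section(vol, 0, f)
        b = extract_cross_section(shifted, 0, fs)
        np.testing.assert_allclose(a.image, b.image)

    def test_invalid_slice_index_rejected(self):
        vol = self.make_volume()
        frame = compute_cut_frame(straight_line(), 0.5)
        with pytest.raises(ValueError):
            extract_cross_section(vol, 5, frame)

    def test_depth_extent_must_be_positive(self):
        vol = self.make_volume()
        frame = compute_cut_frame(straight_line(), 0.5)
        with pytest.raises(ValueError):
            extract_cross_section(vol, 0, frame, depth_extent=0)


def test_default_stations_avoid_canal_voids(small_phantoms):
    """The default cuts sit next to, not on, the canal projections."""
    from mandicort import LandmarkSet
    _, truth = small_phantoms[0]
    line = fit_bone_line(truth.landmarks.bone_line)
    stations = default_stations(line, truth.landmarks, offset_px=6.0)
    assert len(stations) == 2
    for s, canal_pt in zip(stations, truth.landmarks.canal):
        anchor = point_at(line, s)
        assert np.linalg.norm(anchor - canal_pt) > 3.0
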