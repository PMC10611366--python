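"""Phantom generator: geometry, ground truth, determinism, dataset plumbing."""

import numpy as np
import pytest

from mandicort import generate_dataset, generate_phantom, split_dataset
from mandicort.phantom import GeometryError, PhantomSpec, normalized_midpoint_threshold


def ray_cast_thickness(img, point, center, cortical):
    """Oracle: walk outward along the radial ray through `point` and count
    the contiguous cortical run containing it."""
    direction = (np.asarray(point) - np.asarray(center))
    direction = direction / np.linalg.norm(direction)
    ts = np.arange(-15.0, 15.0, 0.25)
    xs = np.clip(np.round(point[0] + ts * direction[0]), 0, img.shape[1] - 1).astype(int)
    ys = np.clip(np.round(point[1] + ts * direction[1]), 0, img.shape[0] - 1).astype(int)
    vals = img[ys, xs]
    on = np.isclose(vals, cortical)
    # run containing t=0
    i0 = len(ts) // 2
    assert on[i0], "bone-line point is not on cortical bone"
    a = i0
    while a > 0 and on[a - 1]:
        a -= 1
    b = i0
    while b < len(ts) - 1 and on[b + 1]:
        b += 1
    return (b - a + 1) * 0.25


class TestGeneratePhantom:
    def test_same_seed_reproduces_volume_and_truth(self):
        spec = PhantomSpec(seed=42)
        v1, t1 = generate_phantom(spec)
        v2, t2 = generate_phantom(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        assert t1.correct_slice == t2.correct_slice
        np.testing.assert_array_equal(t1.landmarks.to_vector(), t2.landmarks.to_vector())

    def test_noise_free_volume_has_exactly_three_intensities(self):
        spec = PhantomSpec(noise_sd=0.0)
        vol, _ = generate_phantom(spec)
        assert set(np.unique(vol.data)) == {spec.background_intensity,
                                            spec.trabecular_intensity,
                                            spec.cortical_intensity}

    @pytest.mark.parametrize("thickness", [2.0, 4.0, 6.0])
    def test_shell_thickness_at_bone_line_points(self, thickness):
        spec = PhantomSpec(noise_sd=0.0, cortical_thickness_px=thickness,
                           arch_radius_px=17.0)
        vol, truth = generate_phantom(spec)
        img = vol.data[truth.correct_slice]
        n_rows, n_cols = img.shape
        center = (n_cols / 2.0, 0.42 * n_rows)
        for pt in truth.landmarks.bone_line:
            measured = ray_cast_thickness(img, pt, center, spec.cortical_intensity)
            assert measured == pytest.approx(thickness, abs=1.0)

    def test_truth_band_contains_correct_slice_and_is_contiguous(self):
        _, truth = generate_phantom(PhantomSpec())
        assert truth.correct_slice in truth.valid_slices
        assert list(truth.valid_slices) == list(
            range(min(truth.valid_slices), max(truth.valid_slices) + 1))

    def test_landmarks_inside_slice_bounds(self):
        vol, truth = generate_phantom(PhantomSpec())
        pts = truth.landmarks.points
        assert np.all(pts >= 0)
        assert np.all(pts[:, 0] <= vol.data.shape[2] - 1)
        assert np.all(pts[:, 1] <= vol.data.shape[1] - 1)

    def test_canal_voids_only_inside_valid_band(self):
        """The labelling criterion is discriminative by construction: only
        band slices carry background pixels strictly inside the outer
        cortical wall (the pierced foramina)."""
        spec = PhantomSpec(noise_sd=0.0)
        vol, truth = generate_phantom(spec)
        n_rows, n_cols = vol.data.shape[1:]
        cx, cy = n_cols / 2.0, 0.42 * n_rows
        yy, xx = np.mgrid[0:n_rows, 0:n_cols]
        r = np.hypot(xx - cx, yy - cy)
        in_span = np.abs(np.arctan2(xx - cx, yy - cy)) <= np.deg2rad(115)
        t = spec.cortical_thickness_px
        def has_void(img, z):
            scale = 1.0 - 0.015 * abs(z - truth.correct_slice)
            ro = spec.outer_radius_px * scale
            wall_interior = in_span & (r > ro - t + 0.6) & (r < ro - 0.6)
            return bool(np.any(np.isclose(img[wall_interior],
                                          spec.background_intensity)))
        for z in range(vol.n_slices):
            assert has_void(vol.data[z], z) == (z in truth.valid_slices)

    def test_oversized_shell_raises_geometry_error(self):
        with pytest.raises(GeometryError):
            generate_phantom(PhantomSpec(grid=(5, 32, 32), arch_radius_px=20.0))

    def test_bad_intensity_order_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(trabecular_intensity=1.5)


class TestDataset:
    def test_n_items_all_truths_valid(self):
        items = generate_dataset(10, seed=3)
        assert len(items) == 10
        for vol, truth in items:
            assert truth.correct_slice in truth.valid_slices
            assert vol.data.ndim == 3

    def test_fixed_seed_reproduces_dataset(self):
        a = generate_dataset(4, seed=9)
        b = generate_dataset(4, seed=9)
        for (va, _), (vb, _) in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_degenerate_ranges_fix_all_parameters(self):
        ranges = {"arch_radius_px": (18.0, 18.0)}
        items = generate_dataset(3, spec_ranges=ranges, seed=5,
                                 base_spec=PhantomSpec(noise_sd=0.0))
        # identical geometry (only the noise seed differs, and noise is off)
        np.testing.assert_array_equal(items[0][0].data, items[1][0].data)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(3, spec_ranges={"arch_radius_px": (20.0, 10.0)})
        with pytest.raises(ValueError):
            generate_dataset(3, spec_ranges={"not_a_field": (0, 1)})


class TestSplit:
    def test_70_30_split_sizes(self):
        items = list(range(100))
        train, val = split_dataset(items, 0.7, seed=0)
        assert len(train) == 70 and len(val) == 30

    def test_partition_is_disjoint_and_complete(self):
        items = list(range(37))
        train, val = split_dataset(items, 0.7, seed=2)
        assert set(train) | set(val) == set(items)
        assert set(train) & set(val) == set()

    def test_same_seed_same_partition(self):
        items = list(range(20))
        assert split_dataset(items, 0.5, seed=7) == split_dataset(items, 0.5, seed=7)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], 0.7)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3], 1.0)


def test_midpoint_threshold_separates_trabecular_from_cortical():
    spec = PhantomSpec(noise_sd=0.0)
    vol, _ = generate_phantom(spec)
    from mandicort import normalize_volume
    nv = normalize_volume(vol)
    thr = normalized_midpoint_threshold(spec)
    vals = np.unique(nv.data)
    assert vals[-1] > thr          # cortical above
    assert np.all(vals[:-1] < thr)  # background + trabecular below
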