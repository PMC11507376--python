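"""Density grid I/O, moving-average smoothing, and point sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edc_compare import (
    DensityGrid,
    MapFormatError,
    UsageError,
    read_map,
    sample_at,
    sample_points,
    smooth_map,
    write_map,
)

from helpers import brute_force_smooth, nearest_index, write_raw_mrc


def random_grid(rng, dims=(7, 7, 7), voxel=(0.86, 0.86, 0.86), origin=(0.0, 0.0, 0.0)):
    return DensityGrid(
        values=rng.normal(size=dims), voxel_size=np.array(voxel), origin=np.array(origin)
    )


class TestMapIO:
    def test_single_cell_round_trip(self, tmp_path):
        g = DensityGrid(np.full((1, 1, 1), 7.0), np.full(3, 0.86), np.zeros(3))
        write_map(g, tmp_path / "one.mrc")
        back = read_map(tmp_path / "one.mrc")
        assert back.dims == (1, 1, 1)
        assert back.values[0, 0, 0] == 7.0

    def test_round_trip_preserves_values_geometry(self, tmp_path, rng):
        g = random_grid(rng, dims=(8, 6, 4), origin=(1.5, -2.0, 3.25))
        write_map(g, tmp_path / "g.mrc")
        back = read_map(tmp_path / "g.mrc")
        # written as float32, so compare at that precision
        np.testing.assert_allclose(back.values, g.values, atol=1e-6)
        np.testing.assert_allclose(back.voxel_size, g.voxel_size, atol=1e-5)
        np.testing.assert_allclose(back.origin, g.origin, atol=1e-6)

    @pytest.mark.parametrize("axis_order", [(1, 2, 3), (3, 1, 2), (2, 3, 1), (3, 2, 1)])
    def test_permuted_axis_files_read_canonically(self, tmp_path, rng, axis_order):
        """Whatever MAPC/MAPR/MAPS says, values come back in x,y,z order."""
        values = rng.normal(size=(8, 6, 4))
        path = tmp_path / "perm.mrc"
        write_raw_mrc(path, values, voxel=(0.86, 0.86, 0.86), axis_order=axis_order)
        grid = read_map(path)
        np.testing.assert_allclose(grid.values, values, atol=1e-6)
        np.testing.assert_allclose(grid.voxel_size, 0.86, atol=1e-6)

    def test_origin_from_header_words(self, tmp_path, rng):
        values = rng.normal(size=(4, 4, 4))
        path = tmp_path / "orig.mrc"
        write_raw_mrc(path, values, voxel=(1.0, 1.0, 1.0), origin=(2.5, -1.0, 4.0))
        grid = read_map(path)
        np.testing.assert_allclose(grid.origin, [2.5, -1.0, 4.0], atol=1e-6)

    def test_bad_axis_order_is_a_format_error(self, tmp_path, rng):
        path = tmp_path / "bad.mrc"
        write_raw_mrc(path, rng.normal(size=(3, 3, 3)), voxel=(1, 1, 1), axis_order=(1, 1, 3))
        with pytest.raises(MapFormatError, match="MAPC/MAPR/MAPS"):
            read_map(path)

    def test_unreadable_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "junk.mrc"
        path.write_bytes(b"not a map")
        with pytest.raises(MapFormatError):
            read_map(path)


class TestSmoothing:
    def test_constant_map_stays_constant_everywhere(self):
        g = DensityGrid(np.full((6, 5, 7), 3.25), np.ones(3), np.zeros(3))
        s = smooth_map(g, window=5)
        assert s.smoothed
        np.testing.assert_allclose(s.values, 3.25, atol=1e-12)

    def test_central_impulse_spreads_over_125_cells(self):
        values = np.zeros((11, 11, 11))
        values[5, 5, 5] = 125.0
        s = smooth_map(DensityGrid(values, np.ones(3), np.zeros(3)), window=5)
        np.testing.assert_allclose(s.values[3:8, 3:8, 3:8], 1.0, atol=1e-12)
        assert s.values[0, 0, 0] == 0.0

    def test_matches_brute_force_on_random_grid(self, rng):
        g = random_grid(rng, dims=(7, 7, 7))
        s = smooth_map(g, window=5)
        np.testing.assert_allclose(s.values, brute_force_smooth(g.values, 5), atol=1e-12)

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_invalid_window_rejected(self, window):
        g = DensityGrid(np.ones((3, 3, 3)), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            smooth_map(g, window=window)

    def test_smoothing_twice_is_a_usage_error(self):
        g = DensityGrid(np.ones((3, 3, 3)), np.ones(3), np.zeros(3))
        with pytest.raises(UsageError):
            smooth_map(smooth_map(g, 3), 3)

    def test_window_one_is_identity(self, rng):
        g = random_grid(rng, dims=(5, 4, 6))
        s = smooth_map(g, window=1)
        np.testing.assert_array_equal(s.values, g.values)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        window=st.sampled_from([3, 5, 7]),
        dims=st.tuples(*(st.integers(1, 6),) * 3),
    )
    def test_bounds_and_affine_equivariance(self, seed, window, dims):
        """min/max never expand, and smoothing commutes with a*g + b."""
        r = np.random.default_rng(seed)
        g = DensityGrid(r.normal(size=dims), np.ones(3), np.zeros(3))
        s = smooth_map(g, window=window)
        assert s.values.min() >= g.values.min() - 1e-12
        assert s.values.max() <= g.values.max() + 1e-12
        a, b = 2.5, -1.25
        scaled = smooth_map(DensityGrid(a * g.values + b, np.ones(3), np.zeros(3)), window)
        np.testing.assert_allclose(scaled.values, a * s.values + b, atol=1e-10)


class TestSampling:
    def test_constant_map_returns_constant_anywhere_inside(self):
        g = DensityGrid(np.full((5, 5, 5), 2.5), np.ones(3), np.zeros(3))
        assert sample_at(g, (1.9, 0.2, 3.7)) == 2.5

    def test_cell_center_returns_that_cell(self, rng):
        g = random_grid(rng, dims=(6, 5, 4), origin=(1.0, 2.0, 3.0))
        assert sample_at(g, g.cell_center(2, 3, 1)) == g.values[2, 3, 1]

    def test_nearest_matches_index_arithmetic_on_random_points(self, rng):
        g = random_grid(rng, dims=(9, 8, 7), voxel=(0.86, 1.0, 1.2), origin=(-2.0, 1.0, 0.5))
        lo = g.origin - 0.49 * g.voxel_size
        hi = g.origin + (np.array(g.dims) - 0.51) * g.voxel_size
        pts = rng.uniform(lo, hi, size=(1000, 3))
        vals, oob = sample_points(g, pts)
        assert not oob.any()
        for p, v in zip(pts, vals):
            assert v == g.values[nearest_index(p, g.origin, g.voxel_size)]

    def test_out_of_bounds_returns_zero_and_is_tallied(self):
        g = DensityGrid(np.full((3, 3, 3), 9.0), np.ones(3), np.zeros(3))
        g.reset_oob_count()
        assert sample_at(g, (100.0, 0.0, 0.0)) == 0.0
        assert g.oob_count == 1

    def test_trilinear_interpolates_between_cell_centers(self):
        values = np.zeros((2, 1, 1))
        values[1, 0, 0] = 4.0
        g = DensityGrid(values, np.ones(3), np.zeros(3))
        assert sample_at(g, (0.5, 0.0, 0.0), mode="trilinear") == pytest.approx(2.0)

    def test_non_finite_point_rejected(self):
        g = DensityGrid(np.ones((3, 3, 3)), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            sample_at(g, (np.nan, 0, 0))


class TestInvariants:
    def test_grid_validation(self):
        with pytest.raises(MapFormatError):
            DensityGrid(np.ones((2, 2)), np.ones(3), np.zeros(3))
        with pytest.raises(MapFormatError):
            DensityGrid(np.ones((2, 2, 2)), np.array([1.0, 0.0, 1.0]), np.zeros(3))
        bad = np.ones((2, 2, 2))
        bad[0, 0, 0] = np.inf
        with pytest.raises(MapFormatError):
            DensityGrid(bad, np.ones(3), np.zeros(3))
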