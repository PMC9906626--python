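"""Voxel lattice conventions and OpenDX round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosolvmap import OUT_OF_BOUNDS, GridSpec, ScalarGrid, read_dx, write_dx
from cosolvmap.grid import DXParseError


class TestVoxelAssignment:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0.49, 0.0, 0.0), (0, 0, 0)),   # floor convention
            ((0.50, 0.0, 0.0), (1, 0, 0)),   # half-open boundary goes up
            ((4.99, 4.99, 4.99), (9, 9, 9)),
        ],
    )
    def test_floor_half_open(self, small_spec, point, expected):
        assert small_spec.voxel_index(point) == expected

    def test_upper_face_is_out_of_bounds(self, small_spec):
        # 5.0/0.5 = index 10 >= shape
        assert small_spec.voxel_index((5.0, 0.0, 0.0)) is OUT_OF_BOUNDS
        assert small_spec.voxel_index((-0.001, 0.0, 0.0)) is OUT_OF_BOUNDS

    def test_nonfinite_point_raises(self, small_spec):
        with pytest.raises(ValueError):
            small_spec.voxel_index((np.nan, 0.0, 0.0))
        with pytest.raises(ValueError):
            small_spec.voxel_indices(np.array([[np.inf, 0, 0]]))

    def test_face_point_assigned_to_exactly_one_voxel(self, small_spec):
        """A point on a voxel face is counted once (no double counting)."""
        pts = np.array([[1.0, 1.5, 2.0]])  # on faces along all three axes
        idx, inside = small_spec.voxel_indices(pts)
        assert inside.all()
        assert tuple(idx[0]) == (2, 3, 4)

    def test_voxel_center_examples(self, small_spec):
        np.testing.assert_allclose(small_spec.voxel_center((0, 0, 0)), (0.25, 0.25, 0.25))
        np.testing.assert_allclose(small_spec.voxel_center((1, 0, 0)), (0.75, 0.25, 0.25))
        with pytest.raises(IndexError):
            small_spec.voxel_center((10, 0, 0))

    def test_center_index_round_trip(self):
        spec = GridSpec((-3.2, 1.0, 7.5), 0.5, (12, 9, 17))
        rng = np.random.default_rng(42)
        idx = np.stack(
            [rng.integers(0, n, size=1000) for n in spec.shape], axis=1
        )
        for i in idx:
            assert spec.voxel_index(spec.voxel_center(i)) == tuple(i)

    @settings(max_examples=200, derandomize=True)
    @given(
        origin=st.tuples(*[st.floats(-50, 50, allow_nan=False)] * 3),
        spacing=st.floats(0.1, 2.0, allow_nan=False),
        frac=st.tuples(*[st.floats(0, 1, exclude_max=True)] * 3),
    )
    def test_any_in_box_point_lands_in_range(self, origin, spacing, frac):
        """Every point strictly inside the lattice maps to an in-range voxel
        whose box contains it."""
        spec = GridSpec(origin, spacing, (7, 5, 3))
        point = np.asarray(origin) + np.asarray(frac) * np.asarray(spec.shape) * spacing
        idx = spec.voxel_index(point)
        assert idx is not OUT_OF_BOUNDS
        lower = np.asarray(origin) + np.asarray(idx) * spacing
        assert np.all(point >= lower - 1e-9)
        assert np.all(point < lower + spacing + 1e-9)

    def test_ravel_unravel(self, small_spec):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, 10, size=(50, 3))
        np.testing.assert_array_equal(small_spec.unravel(small_spec.ravel(idx)), idx)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(origin=(0, 0, 0), spacing=-0.5, shape=(2, 2, 2)),
            dict(origin=(0, 0, 0), spacing=0.5, shape=(0, 2, 2)),
            dict(origin=(np.nan, 0, 0), spacing=0.5, shape=(2, 2, 2)),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GridSpec(**kwargs)

    def test_from_bounds_covers_box(self):
        spec = GridSpec.from_bounds((0, 0, 0), (5, 5, 5), 0.5)
        assert spec.shape == (10, 10, 10)
        np.testing.assert_allclose(spec.upper, (5, 5, 5))


class TestScalarGrid:
    def test_shape_mismatch_rejected(self, small_spec):
        with pytest.raises(ValueError):
            ScalarGrid(small_spec, np.zeros((2, 2, 2)))

    def test_undefined_voxel_not_readable(self, small_spec):
        g = ScalarGrid.full(small_spec, 1.0)
        g.defined_mask[0, 0, 0] = False
        with pytest.raises(ValueError):
            g.value_at((0, 0, 0))
        assert g.n_defined == small_spec.n_voxels - 1


class TestDXRoundTrip:
    def test_zeros_round_trip(self, tmp_path):
        spec = GridSpec((1.0, 2.0, 3.0), 0.5, (2, 2, 2))
        g = ScalarGrid.full(spec, 0.0)
        path = tmp_path / "z.dx"
        write_dx(g, path)
        back = read_dx(path)
        assert back.spec == spec
        np.testing.assert_array_equal(back.values, 0.0)

    def test_random_values_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        spec = GridSpec((-4.0, 0.25, 9.0), 0.5, (5, 4, 3))
        g = ScalarGrid(spec, rng.normal(size=spec.shape) * 10)
        path = tmp_path / "r.dx"
        write_dx(g, path)
        back = read_dx(path)
        assert back.spec == spec
        np.testing.assert_allclose(back.values, g.values, rtol=1e-5)

    def test_sentinel_masks_undefined(self, tmp_path):
        spec = GridSpec((0, 0, 0), 0.5, (3, 3, 3))
        g = ScalarGrid.full(spec, -1.0)
        g.defined_mask[1, 1, 1] = False
        path = tmp_path / "m.dx"
        write_dx(g, path, sentinel_for_undefined=999.0)
        raw = read_dx(path)  # without declaring the sentinel
        assert raw.values[1, 1, 1] == 999.0
        masked = read_dx(path, sentinel_for_undefined=999.0)
        assert not masked.defined_mask[1, 1, 1]
        assert masked.defined_mask.sum() == 26

    def test_hand_written_fixture_z_fastest(self, tmp_path):
        """A minimal DX file authored by hand: values land in C order (z fastest)."""
        text = (
            "object 1 class gridpositions counts 1 2 3\n"
            "origin 0.0 0.0 0.0\n"
            "delta 0.5 0.0 0.0\n"
            "delta 0.0 0.5 0.0\n"
            "delta 0.0 0.0 0.5\n"
            "object 2 class gridconnections counts 1 2 3\n"
            "object 3 class array type double rank 0 items 6 data follows\n"
            "10.0 11.0 12.0\n"
            "20.0 21.0 22.0\n"
        )
        path = tmp_path / "hand.dx"
        path.write_text(text)
        g = read_dx(path)
        assert g.spec.shape == (1, 2, 3)
        # y=0 row is 10,11,12 along z; y=1 row is 20,21,22
        np.testing.assert_array_equal(g.values[0, 0], [10.0, 11.0, 12.0])
        np.testing.assert_array_equal(g.values[0, 1], [20.0, 21.0, 22.0])

    def test_griddata_reads_our_files(self, tmp_path):
        """Cross-check the dialect against the independent gridData parser."""
        from gridData import Grid

        rng = np.random.default_rng(8)
        spec = GridSpec((1.0, -2.0, 0.5), 0.5, (4, 3, 5))
        g = ScalarGrid(spec, rng.normal(size=spec.shape))
        path = str(tmp_path / "x.dx")
        write_dx(g, path)
        other = Grid(path)
        np.testing.assert_allclose(other.grid, g.values, rtol=1e-5)
        np.testing.assert_allclose(other.origin, spec.origin, atol=1e-6)
        np.testing.assert_allclose(other.delta, [0.5, 0.5, 0.5], atol=1e-6)

    @pytest.mark.parametrize(
        "mutation,fragment",
        [
            (lambda t: t.replace("items 6", "items 5"), "items 5"),
            (lambda t: t.replace("20.0 21.0 22.0\n", ""), "6"),
            (lambda t: t.replace("origin 0.0 0.0 0.0\n", ""), "origin"),
            (lambda t: t.replace("delta 0.5 0.0 0.0\n", ""), "delta"),
        ],
    )
    def test_malformed_file_names_problem(self, tmp_path, mutation, fragment):
        text = (
            "object 1 class gridpositions counts 1 2 3\n"
            "origin 0.0 0.0 0.0\n"
            "delta 0.5 0.0 0.0\n"
            "delta 0.0 0.5 0.0\n"
            "delta 0.0 0.0 0.5\n"
            "object 2 class gridconnections counts 1 2 3\n"
            "object 3 class array type double rank 0 items 6 data follows\n"
            "10.0 11.0 12.0\n"
            "20.0 21.0 22.0\n"
        )
        path = tmp_path / "bad.dx"
        path.write_text(mutation(text))
        with pytest.raises(DXParseError) as err:
            read_dx(path)
        assert fragment in str(err.value)
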