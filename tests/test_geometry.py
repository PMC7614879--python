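"""Polygon measures, rasterization and mask overlap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitoshape as ms
from mitoshape.geometry import fold_90, fold_180, polygon_perimeter

from conftest import (
    exact_polygon_jaccard,
    pixel_covariance_orientation,
    regular_polygon,
    star_polygon,
)


class TestOutlineValidation:
    def test_rejects_too_few_vertices(self):
        with pytest.raises(ms.InvalidGeometryError):
            ms.CellOutline(np.array([[0.0, 0.0], [1, 1]]))

    def test_rejects_collinear_zero_area(self):
        with pytest.raises(ms.InvalidGeometryError):
            ms.CellOutline(np.array([[0.0, 0.0], [1, 1], [2, 2]]))

    def test_rejects_self_intersection(self):
        bowtie = np.array([[0.0, 0.0], [1, 1], [1, 0], [0, 1]])
        with pytest.raises(ms.InvalidGeometryError):
            ms.CellOutline(bowtie)

    def test_rejects_nonfinite(self):
        with pytest.raises(ms.InvalidGeometryError):
            ms.CellOutline(np.array([[0.0, 0.0], [1, 0], [np.nan, 1]]))

    def test_drops_duplicate_closing_vertex(self, unit_square):
        closed = np.vstack([unit_square.vertices, unit_square.vertices[0]])
        assert len(ms.CellOutline(closed).vertices) == 4


class TestAreaCentroid:
    def test_unit_square(self, unit_square):
        assert ms.polygon_area(unit_square) == pytest.approx(1.0)
        assert ms.polygon_centroid(unit_square) == pytest.approx([0.5, 0.5])

    def test_orientation_invariance(self, unit_square):
        reversed_sq = ms.CellOutline(unit_square.vertices[::-1])
        assert ms.polygon_area(reversed_sq) == pytest.approx(1.0)
        assert ms.polygon_centroid(reversed_sq) == pytest.approx([0.5, 0.5])

    def test_triangle_closed_form(self, triangle_345):
        assert ms.polygon_area(triangle_345) == pytest.approx(6.0)
        assert ms.polygon_centroid(triangle_345) == pytest.approx([4 / 3, 1.0])


class TestRasterize:
    def test_square_area_within_tolerance(self):
        sq = ms.CellOutline(10.0 * np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]]))
        mask = ms.rasterize(sq, 0.1)
        assert mask.area == pytest.approx(100.0, rel=0.02)

    def test_any_valid_outline_has_foreground(self):
        tri = star_polygon(3, n_vertices=9)
        assert ms.rasterize(tri).grid.sum() > 0

    def test_triangle_shoelace_oracle(self, triangle_345):
        mask = ms.rasterize(triangle_345, 0.05)
        assert mask.area == pytest.approx(6.0, rel=0.02)

    def test_default_resolution_area_error_bound(self):
        shape = star_polygon(11)
        mask = ms.rasterize(shape)
        assert mask.area == pytest.approx(shape.area, rel=0.02)

    def test_zero_pixel_size_rejected(self, unit_square):
        with pytest.raises(ms.InvalidGeometryError):
            ms.rasterize(unit_square, 0.0)


class TestMomentsOrientation:
    def test_axis_aligned_rectangle(self):
        rect = ms.CellOutline(np.array([[0.0, 0.0], [4, 0], [4, 2], [0, 2]]))
        assert ms.moments_orientation(rect) == pytest.approx(0.0)

    def test_rotated_rectangle_against_pixel_oracle(self):
        rect = ms.CellOutline(np.array([[0.0, 0.0], [4, 0], [4, 2], [0, 2]]))
        rot = rect.transformed(rotation_deg=30.0)
        mask = ms.rasterize(rot)
        assert ms.moments_orientation(mask) == pytest.approx(30.0, abs=0.5)
        assert pixel_covariance_orientation(mask) == pytest.approx(30.0, abs=0.5)
        assert ms.moments_orientation(rot) == pytest.approx(30.0, abs=1e-9)

    def test_disc_degenerate_returns_zero(self):
        assert ms.moments_orientation(regular_polygon(128)) == 0.0

    @pytest.mark.parametrize("angle", [10.0, 75.0, 160.0])
    def test_rotation_equivariance_mod_180(self, angle):
        shape = star_polygon(7)
        base = ms.moments_orientation(shape)
        rotated = ms.moments_orientation(shape.transformed(rotation_deg=angle))
        diff = fold_180(rotated - base - angle)
        assert min(diff, 180 - diff) == pytest.approx(0.0, abs=1e-6)

    def test_translation_and_scale_invariance(self):
        shape = star_polygon(8)
        moved = shape.transformed(scale=2.5, translation=(40.0, -13.0))
        assert ms.moments_orientation(moved) == pytest.approx(
            ms.moments_orientation(shape), abs=1e-9
        )


class TestJaccard:
    def test_identical_masks(self, unit_square):
        m = ms.rasterize(unit_square, 0.02)
        assert ms.jaccard_index(m, m) == 1.0

    def test_disjoint_masks(self, unit_square):
        a = ms.rasterize(unit_square, 0.02)
        far = ms.CellOutline(unit_square.vertices + 10.0)
        b = ms.rasterize(far, 0.02)
        assert ms.jaccard_index(a, b) == 0.0

    def test_half_overlapping_squares_closed_form(self, unit_square):
        shifted = ms.CellOutline(unit_square.vertices + np.array([0.5, 0.0]))
        a = ms.rasterize(unit_square, 0.01)
        b = ms.rasterize(shifted, 0.01)
        assert ms.jaccard_index(a, b) == pytest.approx(1 / 3, abs=0.02)

    def test_dissimilarity_and_nonoverlap_area(self, unit_square):
        shifted = ms.CellOutline(unit_square.vertices + np.array([0.5, 0.0]))
        a = ms.rasterize(unit_square, 0.01)
        b = ms.rasterize(shifted, 0.01)
        j, d, nonoverlap = ms.jaccard_detail(a, b)
        assert d == pytest.approx(1.0 - j)
        assert nonoverlap == pytest.approx(1.0, abs=0.05)  # union 1.5 - inter 0.5

    def test_empty_masks_raise(self):
        empty = ms.BinaryMask(np.zeros((4, 4), bool), 1.0, (0.0, 0.0))
        with pytest.raises(ms.EmptyOverlapError):
            ms.jaccard_index(empty, empty)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed_a=st.integers(0, 500), seed_b=st.integers(501, 1000))
    def test_symmetry_bounds_and_exact_oracle(self, seed_a, seed_b):
        """Pixel-count J is symmetric, bounded, and close to the exact
        polygon-overlap value for star polygons sharing a window."""
        a = star_polygon(seed_a, irregularity=0.25)
        b = ms.CellOutline(star_polygon(seed_b, irregularity=0.25).vertices + 4.0)
        ma, mb = ms.rasterize(a, 0.15), ms.rasterize(b, 0.15)
        jab = ms.jaccard_index(ma, mb)
        jba = ms.jaccard_index(mb, ma)
        assert 0.0 <= jab <= 1.0
        assert jab == pytest.approx(jba, abs=0.01)
        assert jab == pytest.approx(exact_polygon_jaccard(a, b), abs=0.02)


class TestFeretAndSegments:
    def test_rectangle_diagonal(self):
        rect = ms.CellOutline(np.array([[0.0, 0.0], [3, 0], [3, 4], [0, 4]]))
        assert ms.feret_length(rect) == pytest.approx(5.0)

    def test_circle_diameter(self):
        assert ms.feret_length(regular_polygon(256, radius=9.0)) == pytest.approx(
            18.0, abs=0.2
        )

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [((0, 0), (1, 1), 45.0), ((0, 0), (5, 0), 0.0), ((2, 1), (1, 2), 135.0)],
    )
    def test_segment_angles(self, p1, p2, expected):
        assert ms.segment_angle(p1, p2) == pytest.approx(expected)
        assert ms.segment_angle(p2, p1) == pytest.approx(expected)

    def test_coincident_points_raise(self):
        with pytest.raises(ms.InvalidGeometryError):
            ms.segment_angle((1.0, 1.0), (1.0, 1.0))


class TestCircularity:
    def test_circle_limit(self):
        assert ms.circularity(regular_polygon(256)) == pytest.approx(1.0, abs=0.001)

    def test_square_closed_form(self, unit_square):
        assert ms.circularity(unit_square) == pytest.approx(math.pi / 4, abs=1e-12)

    def test_elongated_rectangle_closed_form(self):
        # 10x1 rectangle: area 10, perimeter 22
        rect = ms.CellOutline(np.array([[0.0, 0.0], [10, 0], [10, 1], [0, 1]]))
        assert ms.circularity(rect) == pytest.approx(4 * math.pi * 10 / 22**2, abs=1e-12)

    def test_rigid_and_scale_invariance(self):
        shape = star_polygon(21)
        moved = shape.transformed(scale=3.0, rotation_deg=67.0, translation=(5, -9))
        assert ms.circularity(moved) == pytest.approx(ms.circularity(shape), rel=1e-9)


class TestAngleFolding:
    @pytest.mark.parametrize("angle", [-370.0, -91.0, 0.0, 89.9, 90.0, 179.0, 361.0])
    def test_fold_90_range_and_axis_symmetry(self, angle):
        folded = fold_90(angle)
        assert 0.0 <= folded <= 90.0
        assert fold_90(angle + 180.0) == pytest.approx(folded)
        assert fold_90(-angle) == pytest.approx(folded)
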