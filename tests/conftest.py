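"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the implementation paths they check:
polygon overlap uses exact shapely boolean areas (vs pixel counting),
orientation uses brute-force pixel covariance (vs closed-form polygon
moments), and the rank-sum p value enumerates group labelings directly
(vs the recurrence-based null distribution).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from mitoshape.geometry import BinaryMask, CellOutline, rasterize


@pytest.fixture
def unit_square() -> CellOutline:
    return CellOutline(np.array([[0.0, 0.0], [1, 0], [1, 1], [0, 1]]))


@pytest.fixture
def triangle_345() -> CellOutline:
    return CellOutline(np.array([[0.0, 0.0], [4, 0], [0, 3]]))


def star_polygon(
    seed: int, n_vertices: int = 48, irregularity: float = 0.35, radius: float = 18.0
) -> CellOutline:
    """Random star-shaped test polygon (independent of the package's own
    generator: raw radial noise, no smoothing)."""
    rng = np.random.default_rng(seed)
    radii = radius * (1.0 + irregularity * rng.uniform(-1, 1, n_vertices))
    ang = 2 * math.pi * np.arange(n_vertices) / n_vertices
    verts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
    return CellOutline(verts)


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> CellOutline:
    ang = 2 * math.pi * np.arange(n) / n
    return CellOutline(
        np.column_stack(
            [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
        )
    )


def random_convex_polygon(seed: int, n_points: int = 12, scale: float = 15.0) -> CellOutline:
    """Convex hull of random points (oracle-friendly: exact overlap areas)."""
    from scipy.spatial import ConvexHull

    rng = np.random.default_rng(seed)
    pts = rng.uniform(-scale, scale, (n_points, 2))
    hull = ConvexHull(pts)
    return CellOutline(pts[hull.vertices])


def exact_polygon_jaccard(a: CellOutline, b: CellOutline) -> float:
    """Exact intersection-over-union from shapely boolean areas."""
    pa, pb = Polygon(a.vertices), Polygon(b.vertices)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union


def pixel_covariance_orientation(mask: BinaryMask) -> float:
    """Brute-force principal axis of foreground pixel coordinates."""
    iy, ix = np.nonzero(mask.grid)
    coords = np.column_stack([ix, iy]).astype(float)
    coords -= coords.mean(axis=0)
    cov = coords.T @ coords / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    return math.degrees(math.atan2(v[1], v[0])) % 180.0


def brute_force_rank_p(n_a: int, n_b: int, u_obs: float) -> float:
    """Two-tailed p by enumerating all C(n_a+n_b, n_a) labelings of distinct
    values: the fraction with U at least as far from n_a·n_b/2 as u_obs."""
    n = n_a + n_b
    mean = n_a * n_b / 2.0
    dev = abs(u_obs - mean)
    hits = total = 0
    for a_pos in itertools.combinations(range(n), n_a):
        a_set = set(a_pos)
        u = sum(
            1
            for i in a_pos
            for j in range(n)
            if j not in a_set and i > j
        )
        total += 1
        if abs(u - mean) >= dev - 1e-12:
            hits += 1
    return hits / total


def pixel_jaccard_at_rotation(
    reference: CellOutline, moving_parts, pivot, rotation_deg: float, pixel_size: float,
    center, half_width,
) -> float:
    """Overlap objective re-implemented from geometry primitives only (used
    as the exhaustive-grid alignment oracle; independent of the search in
    mitoshape.align)."""
    th = math.radians(-rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    parts = [(np.asarray(v, float) - pivot) @ rot.T + pivot for v in moving_parts]
    ref_mask = rasterize([reference.vertices], pixel_size, center=center, half_width=half_width)
    mov_mask = rasterize(parts, pixel_size, center=center, half_width=half_width)
    inter = np.count_nonzero(ref_mask.grid & mov_mask.grid)
    union = np.count_nonzero(ref_mask.grid | mov_mask.grid)
    return inter / union if union else 0.0
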