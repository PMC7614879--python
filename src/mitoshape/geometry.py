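"""Planar shape representation and morphometrics for cell footprints.

Coordinates are physical micrometres in a right-handed, math-style frame
(x right, y up); angles are measured counter-clockwise from the +x axis.
Importers of image-convention data (y down) must flip y before constructing
these objects — see :mod:`mitoshape.io`.

The central objects are :class:`CellOutline` (an ordered simple polygon, the
unit of manual segmentation) and :class:`BinaryMask` (its rasterization on a
physical pixel grid, the unit of overlap computation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from shapely.geometry import Polygon

from .errors import InvalidGeometryError

__all__ = [
    "CellOutline",
    "BinaryMask",
    "rasterize",
    "polygon_area",
    "polygon_centroid",
    "polygon_perimeter",
    "moments_orientation",
    "jaccard_index",
    "jaccard_detail",
    "feret_length",
    "segment_angle",
    "circularity",
    "fold_180",
    "fold_90",
    "default_pixel_size",
]

#: Grid points across the bounding-circle diameter at the default resolution.
DEFAULT_RESOLUTION = 256

#: Relative eigenvalue gap below which a shape's principal axes are treated
#: as degenerate (disc-like) and orientation is reported as 0 by convention.
DEGENERACY_TOLERANCE = 0.01


def fold_180(angle_deg: float) -> float:
    """Fold an angle to the axis range [0, 180)."""
    return float(np.mod(angle_deg, 180.0))


def fold_90(angle_deg: float) -> float:
    """Fold an angle to the unsigned tilt range [0, 90]."""
    a = fold_180(angle_deg)
    return float(180.0 - a if a > 90.0 else a)


@dataclass(frozen=True)
class CellOutline:
    """One cell footprint at one timepoint: an ordered simple polygon.

    Parameters
    ----------
    vertices
        (n, 2) array of (x, y) positions in micrometres, n >= 3, implicitly
        closed.  A duplicated closing vertex is dropped on construction.
    frame_time
        Acquisition time in minutes.
    pixel_size
        Preferred rasterization pitch in µm/px; ``None`` selects the
        resolution-adaptive default (bounding-circle diameter / 256).
    cell_id, frame_index
        Identifiers carried through to tidy outputs.
    """

    vertices: np.ndarray
    frame_time: float = 0.0
    pixel_size: float | None = None
    cell_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidGeometryError("vertices must be an (n, 2) array")
        if not np.all(np.isfinite(v)):
            raise InvalidGeometryError("vertex coordinates must be finite")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise InvalidGeometryError("outline needs at least 3 distinct vertices")
        poly = Polygon(v)
        if poly.area <= 0.0:
            raise InvalidGeometryError("outline encloses zero area")
        if not poly.is_valid or not poly.is_simple:
            raise InvalidGeometryError("outline is self-intersecting")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    # -- geometric properties ------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return polygon_area(self)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self)

    @property
    def perimeter(self) -> float:
        return polygon_perimeter(self)

    def transformed(
        self,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: Sequence[float] = (0.0, 0.0),
        origin: Sequence[float] | None = None,
    ) -> "CellOutline":
        """Similarity transform applied to the vertices (exact, no raster).

        Scaling and rotation are performed about ``origin`` (default: the
        area centroid), then the translation is added.
        """
        if scale <= 0:
            raise InvalidGeometryError("scale must be positive")
        o = np.asarray(origin if origin is not None else self.centroid, float)
        th = math.radians(rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        v = (self.vertices - o) * scale @ rot.T + o + np.asarray(translation, float)
        return replace(self, vertices=v)


def _as_vertex_arrays(shape) -> list[np.ndarray]:
    """Normalize a footprint (outline, vertex array, or iterable of either)
    into a list of (n, 2) vertex arrays."""
    if isinstance(shape, CellOutline):
        return [np.asarray(shape.vertices, float)]
    if isinstance(shape, np.ndarray) and shape.ndim == 2:
        return [np.asarray(shape, float)]
    out: list[np.ndarray] = []
    for part in shape:  # type: ignore[union-attr]
        if isinstance(part, CellOutline):
            out.append(np.asarray(part.vertices, float))
        else:
            out.append(np.asarray(part, float))
    if not out:
        raise InvalidGeometryError("empty footprint")
    return out


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster of a footprint on a physical grid.

    ``grid[iy, ix]`` covers the pixel whose *center* is
    ``origin + (ix, iy) * pixel_size`` (y increases with row index; the
    math-style frame is kept so no vertical flip is ever needed).
    """

    grid: np.ndarray
    pixel_size: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2:
            raise InvalidGeometryError("mask grid must be 2-D")
        if self.pixel_size <= 0:
            raise InvalidGeometryError("pixel_size must be positive")
        g.setflags(write=False)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def area(self) -> float:
        """Foreground area in µm² (pixel count × pixel_size²)."""
        return float(self.grid.sum()) * self.pixel_size**2

    @property
    def centroid(self) -> np.ndarray:
        iy, ix = np.nonzero(self.grid)
        if len(ix) == 0:
            raise InvalidGeometryError("empty mask has no centroid")
        return np.array(
            [
                self.origin[0] + ix.mean() * self.pixel_size,
                self.origin[1] + iy.mean() * self.pixel_size,
            ]
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid.shape
        xs = self.origin[0] + np.arange(nx) * self.pixel_size
        ys = self.origin[1] + np.arange(ny) * self.pixel_size
        return xs, ys


def default_pixel_size(shapes, resolution: int = DEFAULT_RESOLUTION) -> float:
    """Resolution-adaptive pitch: bounding-circle diameter / ``resolution``.

    The bounding circle is taken about the joint vertex centroid of all
    footprint parts, which encloses every vertex by construction.
    """
    parts = []
    for s in shapes if isinstance(shapes, (list, tuple)) else [shapes]:
        parts.extend(_as_vertex_arrays(s))
    allv = np.vstack(parts)
    c = allv.mean(axis=0)
    radius = float(np.max(np.linalg.norm(allv - c, axis=1)))
    if radius <= 0:
        raise InvalidGeometryError("degenerate footprint")
    return 2.0 * radius / resolution


def rasterize(
    shape,
    pixel_size: float | None = None,
    center: Sequence[float] | None = None,
    half_width: float | None = None,
) -> BinaryMask:
    """Rasterize a footprint (one outline or several) onto a square grid.

    A pixel is foreground iff its center lies inside a footprint polygon
    under a half-open even-odd rule: centers falling exactly on a boundary
    edge count as inside on the lower/left side and outside on the
    upper/right (implemented by testing containment at the center nudged by
    +1e-6 pixel in x and y), so abutting shapes tile without double
    counting and axis-aligned edges are not systematically dropped.  The
    window is a square centered on the footprint centroid — or on
    ``center`` — padded so the shape still fits after an arbitrary rotation
    about that center.
    """
    parts = _as_vertex_arrays(shape)
    geoms = []
    for v in parts:
        p = Polygon(v)
        if p.area <= 0:
            raise InvalidGeometryError("cannot rasterize a zero-area polygon")
        geoms.append(p)
    geom = shapely.union_all(geoms)
    if pixel_size is None:
        pixel_size = default_pixel_size(parts)
    if pixel_size <= 0:
        raise InvalidGeometryError("pixel_size must be positive")
    allv = np.vstack(parts)
    c = np.asarray(center, float) if center is not None else allv.mean(axis=0)
    if half_width is None:
        half_width = float(np.max(np.linalg.norm(allv - c, axis=1))) + 2 * pixel_size
    n = int(math.ceil(2 * half_width / pixel_size)) + 1
    origin = (c[0] - (n - 1) / 2 * pixel_size, c[1] - (n - 1) / 2 * pixel_size)
    xs = origin[0] + np.arange(n) * pixel_size
    ys = origin[1] + np.arange(n) * pixel_size
    eps = 1e-6 * pixel_size  # half-open boundary rule
    xx, yy = np.meshgrid(xs + eps, ys + eps)
    shapely.prepare(geom)
    grid = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(n, n)
    return BinaryMask(grid=grid, pixel_size=pixel_size, origin=origin)


# -- polygon scalar measures -------------------------------------------------


def _signed_area_centroid(v: np.ndarray) -> tuple[float, np.ndarray]:
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if a == 0:
        raise InvalidGeometryError("degenerate polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    return float(a), np.array([cx, cy])


def polygon_area(outline) -> float:
    """Enclosed area in µm² (shoelace formula, orientation independent)."""
    parts = _as_vertex_arrays(outline)
    if len(parts) == 1:
        a, _ = _signed_area_centroid(parts[0])
        return abs(a)
    return float(shapely.union_all([Polygon(p) for p in parts]).area)


def polygon_centroid(outline) -> np.ndarray:
    """Area centroid (x, y) in µm."""
    parts = _as_vertex_arrays(outline)
    if len(parts) == 1:
        _, c = _signed_area_centroid(parts[0])
        return c
    u = shapely.union_all([Polygon(p) for p in parts])
    return np.array([u.centroid.x, u.centroid.y])


def polygon_perimeter(outline) -> float:
    v = _as_vertex_arrays(outline)[0]
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def _polygon_central_moments(v: np.ndarray) -> np.ndarray:
    """Per-unit-area central second moments [[µ20, µ11], [µ11, µ02]] of a
    polygon, from the closed-form integrals over the enclosed region."""
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if a == 0:
        raise InvalidGeometryError("degenerate polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * a)
    cy = ((y + y1) * cross).sum() / (6.0 * a)
    sxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    syy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mu20 = sxx / a - cx * cx
    mu02 = syy / a - cy * cy
    mu11 = sxy / a - cx * cy
    return np.array([[mu20, mu11], [mu11, mu02]])


def _mask_central_moments(mask: BinaryMask) -> np.ndarray:
    iy, ix = np.nonzero(mask.grid)
    if len(ix) == 0:
        raise InvalidGeometryError("empty mask")
    x = ix * mask.pixel_size
    y = iy * mask.pixel_size
    x = x - x.mean()
    y = y - y.mean()
    return np.array(
        [[np.mean(x * x), np.mean(x * y)], [np.mean(x * y), np.mean(y * y)]]
    )


def moments_orientation(shape) -> float:
    """Principal-axis orientation from second-order central moments, in
    degrees counter-clockwise from +x, folded to [0, 180).

    For outlines the moments are the exact polygon integrals; for masks they
    are pixel moments.  Rotationally degenerate shapes (principal-moment gap
    below 1 % of the trace, e.g. discs and squares) return 0 by convention.
    """
    if isinstance(shape, BinaryMask):
        mu = _mask_central_moments(shape)
    else:
        parts = _as_vertex_arrays(shape)
        if len(parts) == 1:
            mu = _polygon_central_moments(parts[0])
        else:
            # footprint union: moments of the union region via rasterization
            mu = _mask_central_moments(rasterize(shape))
    evals = np.linalg.eigvalsh(mu)
    trace = evals.sum()
    if trace <= 0 or (evals[1] - evals[0]) < DEGENERACY_TOLERANCE * trace:
        return 0.0
    theta = 0.5 * math.atan2(2.0 * mu[0, 1], mu[0, 0] - mu[1, 1])
    return fold_180(math.degrees(theta))


# -- mask overlap ------------------------------------------------------------


def _resample_onto(mask: BinaryMask, pixel_size, origin, shape) -> np.ndarray:
    """Nearest-neighbour lookup of ``mask`` on a target lattice."""
    ny, nx = shape
    xs = origin[0] + np.arange(nx) * pixel_size
    ys = origin[1] + np.arange(ny) * pixel_size
    jx = np.rint((xs - mask.origin[0]) / mask.pixel_size).astype(int)
    jy = np.rint((ys - mask.origin[1]) / mask.pixel_size).astype(int)
    okx = (jx >= 0) & (jx < mask.grid.shape[1])
    oky = (jy >= 0) & (jy < mask.grid.shape[0])
    out = np.zeros((ny, nx), dtype=bool)
    sub = mask.grid[np.ix_(jy[oky], jx[okx])]
    out[np.ix_(oky, okx)] = sub
    return out


def _common_grids(a: BinaryMask, b: BinaryMask) -> tuple[np.ndarray, np.ndarray, float]:
    """Resample both masks onto one lattice (pitch of ``a``, aligned to a's
    pixel centers, covering both extents)."""
    ps = a.pixel_size
    same = (
        b.pixel_size == ps
        and b.grid.shape == a.grid.shape
        and np.allclose(b.origin, a.origin)
    )
    if same:
        return a.grid, b.grid, ps

    def extent(m: BinaryMask):
        ny, nx = m.grid.shape
        return (
            m.origin[0],
            m.origin[1],
            m.origin[0] + (nx - 1) * m.pixel_size,
            m.origin[1] + (ny - 1) * m.pixel_size,
        )

    ax0, ay0, ax1, ay1 = extent(a)
    bx0, by0, bx1, by1 = extent(b)
    x0 = ax0 + math.floor((min(ax0, bx0) - ax0) / ps) * ps
    y0 = ay0 + math.floor((min(ay0, by0) - ay0) / ps) * ps
    x1, y1 = max(ax1, bx1), max(ay1, by1)
    nx = int(round((x1 - x0) / ps)) + 1
    ny = int(round((y1 - y0) / ps)) + 1
    ga = _resample_onto(a, ps, (x0, y0), (ny, nx))
    gb = _resample_onto(b, ps, (x0, y0), (ny, nx))
    return ga, gb, ps


def jaccard_detail(a: BinaryMask, b: BinaryMask) -> tuple[float, float, float]:
    """(jaccard, dissimilarity, nonoverlap_area µm²) by pixel counting.

    Masks on different grids are first resampled (nearest neighbour) onto a
    shared lattice at the pitch of ``a``.
    """
    from .errors import EmptyOverlapError

    ga, gb, ps = _common_grids(a, b)
    inter = int(np.count_nonzero(ga & gb))
    union = int(np.count_nonzero(ga | gb))
    if union == 0:
        raise EmptyOverlapError("Jaccard undefined: both masks are empty")
    j = inter / union
    return j, 1.0 - j, (union - inter) * ps**2


def jaccard_index(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection-over-union of two masks, in [0, 1]; symmetric."""
    return jaccard_detail(a, b)[0]


# -- caliper and segment measures -------------------------------------------


def feret_length(outline) -> float:
    """Maximum caliper distance (Feret diameter) over convex-hull vertices."""
    v = np.vstack(_as_vertex_arrays(outline))
    if len(np.unique(v, axis=0)) < 3:
        raise InvalidGeometryError("Feret length needs a non-degenerate outline")
    hull = v[ConvexHull(v).vertices]
    return float(pdist(hull).max())


def segment_angle(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Orientation of the segment p1→p2 from +x, folded to [0, 180)."""
    d = np.asarray(p2, float) - np.asarray(p1, float)
    if np.allclose(d, 0):
        raise InvalidGeometryError("segment endpoints coincide")
    return fold_180(math.degrees(math.atan2(d[1], d[0])))


def circularity(outline) -> float:
    """4π·area / perimeter² on the polygon: 1 for a circle (many-vertex
    limit), decreasing with elongation or lobing."""
    a = polygon_area(outline)
    p = polygon_perimeter(outline)
    if p <= 0:
        raise InvalidGeometryError("degenerate polygon")
    return 4.0 * math.pi * a / (p * p)
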