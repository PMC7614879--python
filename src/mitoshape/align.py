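"""Intrinsic-shape comparison of cell footprints.

Two footprints are compared by their raster overlap (Jaccard index) after
removing, in order, the contributions of

1. *area*       — the moving footprint is uniformly scaled about its
                  centroid so both areas are equal,
2. *displacement* — it is translated so the centroids coincide,
3. *orientation*  — it is rotated about the common centroid to the angle
                  that maximizes the Jaccard index.

With all three removed the residual dissimilarity 1 − J reflects intrinsic
shape change only.  The rotation search is a 2° grid over [0, 360) seeded
additionally with the two moment-orientation candidates, followed by local
refinement to 0.1°; ties are broken toward the smallest non-negative angle.
Transforms are always applied to polygon vertices (exact), never to rasters,
so no interpolation loss enters the search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import InvalidGeometryError
from .geometry import (
    CellOutline,
    _as_vertex_arrays,
    default_pixel_size,
    fold_180,
    moments_orientation,
    rasterize,
)

__all__ = ["AlignmentResult", "align_intrinsic", "ALL_COMPONENTS"]

ALL_COMPONENTS = frozenset({"area", "displacement", "orientation"})


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of intrinsic-shape alignment.

    ``rotation`` is the detected misorientation of the moving footprint
    relative to the reference, in degrees CCW in [0, 360): rotating the
    moving footprint by ``-rotation`` about the common centroid produces the
    maximal overlap.  A copy of the reference rotated by +30° therefore
    reports ``rotation == 30``.  ``scale_factor`` is the factor applied to
    the moving footprint (0.5 when it was twice the reference size) and
    ``translation`` the shift applied to its centroid.
    """

    jaccard: float
    dissimilarity: float
    nonoverlap_area: float
    scale_factor: float
    translation: tuple[float, float]
    rotation: float
    components_removed: frozenset[str]
    pixel_size: float

    def __post_init__(self) -> None:
        assert -1e-9 <= self.jaccard <= 1 + 1e-9
        assert self.scale_factor > 0


def _footprint_geom(shape):
    parts = [Polygon(v) for v in _as_vertex_arrays(shape)]
    for p in parts:
        if p.area <= 0 or not p.is_valid:
            raise InvalidGeometryError("degenerate footprint polygon")
    return shapely.union_all(parts)


def _rotate_parts(parts, angle_deg, pivot):
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return [(v - pivot) @ rot.T + pivot for v in parts]


def _overlap_counts(ref_grid: np.ndarray, mov_grid: np.ndarray) -> tuple[int, int]:
    inter = int(np.count_nonzero(ref_grid & mov_grid))
    union = int(np.count_nonzero(ref_grid | mov_grid))
    return inter, union


def rotation_objective(ref_mask, mov_parts, pivot, pixel_size, center, half_width):
    """Return f(rotation_deg) -> Jaccard of the rotated moving footprint
    against a fixed reference mask, both rasterized on the same window.

    ``rotation_deg`` is the *reported* misorientation; the applied vertex
    rotation is its negation.  Exposed for exhaustive-grid cross-checks.
    """

    def f(rotation_deg: float) -> float:
        parts = _rotate_parts(mov_parts, -rotation_deg, pivot)
        m = rasterize(parts, pixel_size, center=center, half_width=half_width)
        inter, union = _overlap_counts(ref_mask.grid, m.grid)
        return inter / union if union else 0.0

    return f


def align_intrinsic(
    reference,
    moving,
    components=ALL_COMPONENTS,
    pixel_size: float | None = None,
    coarse_step: float = 2.0,
    refine_step: float = 0.1,
) -> AlignmentResult:
    """Align ``moving`` onto ``reference`` and score the residual overlap.

    Parameters
    ----------
    reference, moving
        A :class:`~mitoshape.geometry.CellOutline`, an (n, 2) vertex array,
        or a list of either (a multi-part footprint, e.g. the union of two
        daughter cells).  Multi-part footprints are combined by logical OR
        at the raster stage.
    components
        Which contributions to remove; the full set gives the
        shape-contribution-only comparison.
    pixel_size
        Raster pitch in µm/px; default is bounding-circle diameter / 256 of
        the joint footprint.
    coarse_step, refine_step
        Rotation-search grid steps in degrees.

    Returns
    -------
    AlignmentResult
        Jaccard/dissimilarity of the best alignment plus the transform.
    """
    components = frozenset(components)
    unknown = components - ALL_COMPONENTS
    if unknown:
        raise InvalidGeometryError(f"unknown alignment components: {sorted(unknown)}")

    ref_parts = _as_vertex_arrays(reference)
    mov_parts = _as_vertex_arrays(moving)
    ref_geom = _footprint_geom(ref_parts)
    mov_geom = _footprint_geom(mov_parts)

    ref_c = np.array([ref_geom.centroid.x, ref_geom.centroid.y])
    mov_c = np.array([mov_geom.centroid.x, mov_geom.centroid.y])

    scale = math.sqrt(ref_geom.area / mov_geom.area) if "area" in components else 1.0
    mov_parts = [(v - mov_c) * scale + mov_c for v in mov_parts]

    if "displacement" in components:
        translation = ref_c - mov_c
        mov_parts = [v + translation for v in mov_parts]
        pivot = ref_c
    else:
        translation = np.zeros(2)
        pivot = mov_c

    # Common square window: centered between the footprints, wide enough for
    # the reference and for any rotation of the moving footprint about pivot.
    allv = np.vstack(ref_parts + mov_parts)
    center = allv.mean(axis=0) if "displacement" not in components else ref_c
    r_ref = float(np.max(np.linalg.norm(np.vstack(ref_parts) - center, axis=1)))
    r_mov = float(
        np.max(np.linalg.norm(np.vstack(mov_parts) - pivot, axis=1))
        + np.linalg.norm(pivot - center)
    )
    if pixel_size is None:
        pixel_size = default_pixel_size([np.vstack(ref_parts), np.vstack(mov_parts)])
    half_width = max(r_ref, r_mov) + 2 * pixel_size

    ref_mask = rasterize(ref_parts, pixel_size, center=center, half_width=half_width)

    rotation = 0.0
    if "orientation" in components and coarse_step > 0:
        theta_ref = moments_orientation(reference)
        theta_mov = moments_orientation(moving)
        seeds = [fold_180(theta_mov - theta_ref)]
        seeds.append(seeds[0] + 180.0)
        coarse = np.arange(0.0, 360.0, coarse_step)
        candidates = np.unique(np.sort(np.concatenate([coarse, seeds])))

        # coarse pass at half resolution, then local refinement at full
        ref_coarse = rasterize(
            ref_parts, 2 * pixel_size, center=center, half_width=half_width
        )
        f_coarse = rotation_objective(
            ref_coarse, mov_parts, pivot, 2 * pixel_size, center, half_width
        )
        best_r, best_j = 0.0, -1.0
        for r in candidates:
            j = f_coarse(float(r))
            if j > best_j:  # first (smallest) angle wins ties
                best_r, best_j = float(r), j

        f_full = rotation_objective(
            ref_mask, mov_parts, pivot, pixel_size, center, half_width
        )
        lo = best_r - coarse_step
        fine = lo + refine_step * np.arange(
            0, int(round(2 * coarse_step / refine_step)) + 1
        )
        fine = np.unique(np.sort(np.mod(fine, 360.0)))
        rotation, best_j = 0.0, -1.0
        for r in fine:
            j = f_full(float(r))
            if j > best_j:
                rotation, best_j = float(r), j
        mov_parts = _rotate_parts(mov_parts, -rotation, pivot)

    mov_mask = rasterize(mov_parts, pixel_size, center=center, half_width=half_width)
    inter, union = _overlap_counts(ref_mask.grid, mov_mask.grid)
    j = inter / union if union else 0.0
    return AlignmentResult(
        jaccard=j,
        dissimilarity=1.0 - j,
        nonoverlap_area=(union - inter) * pixel_size**2,
        scale_factor=scale,
        translation=(float(translation[0]), float(translation[1])),
        rotation=float(np.mod(rotation, 360.0)),
        components_removed=components,
        pixel_size=pixel_size,
    )
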