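"""Spindle and division-axis angular statistics.

All angles are unsigned, axis-like quantities folded into [0, 90]°: the
substrate defines 0°, so a spindle lying in the substrate plane scores 0 and
a perpendicular one 90.  Spindle poles are consumed as already-projected
planar (x, z) coordinates from maximum-intensity x-z projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidGeometryError,
    MissingFrameError,
)
from .geometry import (
    CellOutline,
    circularity,
    fold_90,
    polygon_area,
    polygon_centroid,
    segment_angle,
)

__all__ = [
    "SpindleTrack",
    "OrientationMetrics",
    "SpheroidFrame",
    "spindle_angle",
    "angle_series",
    "angle_at",
    "cumulative_angle_change",
    "metaphase_plate_angle",
    "spheroid_division_angle",
    "spheroid_morphometrics",
]

#: Tilt above which a spindle counts as misoriented (">30° from substrate").
DEFAULT_TILT_THRESHOLD = 30.0


def spindle_angle(pole1: Sequence[float], pole2: Sequence[float]) -> float:
    """Unsigned tilt of the pole-pole axis from the substrate (x axis),
    folded to [0, 90]°; invariant to pole labelling and to the sign of Δz."""
    d = np.asarray(pole2, float) - np.asarray(pole1, float)
    if np.allclose(d, 0):
        raise InvalidGeometryError("spindle poles coincide")
    return fold_90(math.degrees(math.atan2(d[1], d[0])))


@dataclass
class SpindleTrack:
    """x-z pole-pair coordinates over time with an anaphase anchor.

    ``frames`` is a time-ordered list of ((x, z), (x, z)) pole pairs in µm;
    ``anaphase_onset_frame`` is a positional index into it.
    """

    frames: list[tuple[tuple[float, float], tuple[float, float]]]
    frame_interval: float = 3.0
    anaphase_onset_frame: int = 0
    track_id: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ConfigurationError("spindle track has no frames")
        if not 0 <= self.anaphase_onset_frame < len(self.frames):
            raise ConfigurationError("anaphase_onset_frame outside track range")
        for p1, p2 in self.frames:
            if np.allclose(np.asarray(p1, float), np.asarray(p2, float)):
                raise InvalidGeometryError("spindle poles coincide in a frame")

    def angles(self) -> np.ndarray:
        return np.array([spindle_angle(p1, p2) for p1, p2 in self.frames])

    def offsets(self) -> np.ndarray:
        """Per-frame offsets (min) relative to anaphase onset."""
        return (
            np.arange(len(self.frames)) - self.anaphase_onset_frame
        ) * self.frame_interval


@dataclass
class OrientationMetrics:
    """Angular summary of one spindle track."""

    angle_series: list[tuple[float, float]]  # (offset min, degrees in [0, 90])
    angle_at_21: float | None
    cumulative_change: float
    misoriented: bool
    tilt_threshold: float = DEFAULT_TILT_THRESHOLD


def angle_at(
    track: SpindleTrack, offset_min: float = 21.0
) -> float:
    """Spindle angle at the frame nearest to ``offset_min`` after onset
    (accepted within half the frame interval)."""
    offsets = track.offsets()
    k = int(np.argmin(np.abs(offsets - offset_min)))
    if abs(offsets[k] - offset_min) > track.frame_interval / 2 + 1e-9:
        raise MissingFrameError(
            f"no spindle frame within {track.frame_interval / 2:g} min of "
            f"offset {offset_min:+g} min"
        )
    return float(track.angles()[k])


def angle_series(
    track: SpindleTrack,
    tilt_threshold: float = DEFAULT_TILT_THRESHOLD,
    classify_offset_min: float = 21.0,
) -> OrientationMetrics:
    """Per-frame tilt series plus the standard summary quantities.

    ``angle_at_21`` is the tilt at +21 min by the nearest-frame rule
    (``None`` when the track ends earlier).  ``misoriented`` applies the
    strict > threshold to the tilt at the classification offset, falling
    back to the last available frame for shorter tracks.
    """
    angles = track.angles()
    offsets = track.offsets()
    try:
        at21 = angle_at(track, classify_offset_min)
        classify_angle = at21
    except MissingFrameError:
        at21 = None
        classify_angle = float(angles[-1])
    cum = cumulative_angle_change(track) if len(angles) >= 2 else 0.0
    return OrientationMetrics(
        angle_series=list(zip(offsets.tolist(), angles.tolist())),
        angle_at_21=at21,
        cumulative_change=cum,
        misoriented=bool(classify_angle > tilt_threshold),
        tilt_threshold=tilt_threshold,
    )


def cumulative_angle_change(track: SpindleTrack) -> float:
    """Total angular path Σ|θ(tᵢ₊₁) − θ(tᵢ)| over the folded series, from
    first spindle appearance (first frame) to track end."""
    if len(track.frames) < 2:
        raise InsufficientDataError("cumulative change needs at least 2 frames")
    return float(np.abs(np.diff(track.angles())).sum())


def metaphase_plate_angle(
    plate_segment: tuple[Sequence[float], Sequence[float]],
    substrate_axis: Sequence[float] = (1.0, 0.0),
) -> float:
    """Folded angle between the metaphase-plate segment and the substrate
    direction, in [0, 90]°.

    Note the reading: an in-plane division has its plate *perpendicular* to
    the substrate, so well-oriented divisions score close to 90°.
    """
    p1, p2 = plate_segment
    plate = segment_angle(p1, p2)
    substrate = segment_angle((0.0, 0.0), substrate_axis)
    return fold_90(plate - substrate)


@dataclass
class SpheroidFrame:
    """Spheroid outline plus one dividing cell's position and chromosome
    axis, for division-angle measurement."""

    outline: CellOutline
    division_point: tuple[float, float] | None = None
    chromosome_axis: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.division_point is not None:
            from shapely.geometry import Point

            if not self.outline.polygon.contains(Point(*self.division_point)):
                raise InvalidGeometryError(
                    "division_point lies outside the spheroid outline"
                )
        if self.chromosome_axis is not None:
            a, b = self.chromosome_axis
            if np.allclose(np.asarray(a, float), np.asarray(b, float)):
                raise InvalidGeometryError("chromosome axis is degenerate")


def spheroid_division_angle(frame: SpheroidFrame) -> float:
    """Division angle relative to the spheroid centroid-periphery axis.

    The radial axis is the line from the spheroid centroid through the
    dividing cell (extended to the boundary; only its direction matters).
    The result is the folded difference between the Feret-style orientations
    of that radial axis and of the chromosome axis, in [0, 90]°: 0 means the
    chromosomes lie along the radial axis, 90 perpendicular to it.
    """
    if frame.division_point is None or frame.chromosome_axis is None:
        raise ConfigurationError(
            "spheroid frame needs division_point and chromosome_axis"
        )
    c = polygon_centroid(frame.outline)
    d = np.asarray(frame.division_point, float) - c
    if np.allclose(d, 0):
        raise InvalidGeometryError(
            "division point coincides with the spheroid centroid"
        )
    radial = segment_angle(c, frame.division_point)
    chrom = segment_angle(*frame.chromosome_axis)
    return fold_90(radial - chrom)


def spheroid_morphometrics(outline) -> tuple[float, float]:
    """(cross-sectional area µm², circularity) of a spheroid outline."""
    o = outline.outline if isinstance(outline, SpheroidFrame) else outline
    return polygon_area(o), circularity(o)
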