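"""Event-anchored analysis of mitotic exit.

All metrics are anchored on anaphase onset.  The timing convention is
explicit because live imaging can place t = 0 either on the first frame with
visible anaphase elongation or on the frame before it:

``first_elongation`` (default)
    onset anchor = the first frame with visible elongation (the annotated
    ``anaphase_onset_frame``); the metaphase reference is the frame
    immediately before it; all "+k min" offsets count from the anchor.
``frame_before``
    onset anchor = the frame immediately before first elongation, which is
    also the metaphase reference.

Offsets are resolved to the nearest frame, accepted when within half the
frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .align import ALL_COMPONENTS, align_intrinsic
from .errors import ConfigurationError, InsufficientDataError, MissingFrameError
from .geometry import (
    CellOutline,
    feret_length,
    fold_90,
    moments_orientation,
    polygon_area,
)

__all__ = [
    "CellTrack",
    "DivisionEvent",
    "ExitMetrics",
    "ShapeChangeStep",
    "anchor_times",
    "frame_at_offset",
    "respread_ratio",
    "shape_change_series",
    "mother_similarity_series",
    "mother_similarity",
    "daughter_area_ratio",
    "classify_symmetry",
    "metaphase_feret",
    "exit_metrics",
]

OnsetConvention = Literal["first_elongation", "frame_before"]

#: Default offset (min) of the mother-shape reference before NEB.
MOTHER_REFERENCE_BEFORE_NEB_MIN = 15.0


@dataclass
class CellTrack:
    """Time-ordered footprints of one cell with mitotic timing anchors.

    ``anaphase_onset_frame`` / ``neb_frame`` are *frame indices* (matching
    ``CellOutline.frame_index``), not list positions.
    """

    outlines: list[CellOutline]
    frame_interval: float = 5.0
    neb_frame: int | None = None
    anaphase_onset_frame: int | None = None

    def __post_init__(self) -> None:
        if not self.outlines:
            raise ConfigurationError("track has no outlines")
        times = np.array([o.frame_time for o in self.outlines], float)
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ConfigurationError("frame times must be strictly increasing")
            if np.any(np.abs(dt - self.frame_interval) > 0.01 * self.frame_interval):
                raise ConfigurationError(
                    "non-uniform frame spacing beyond 1 % tolerance"
                )
        idx = [o.frame_index for o in self.outlines]
        if self.anaphase_onset_frame is not None and not (
            min(idx) <= self.anaphase_onset_frame <= max(idx) + 1
        ):
            raise ConfigurationError("anaphase_onset_frame outside track range")

    @property
    def frame_indices(self) -> list[int]:
        return [o.frame_index for o in self.outlines]

    def outline_at_index(self, frame_index: int) -> CellOutline:
        for o in self.outlines:
            if o.frame_index == frame_index:
                return o
        raise MissingFrameError(f"no outline at frame index {frame_index}")

    def time_of_index(self, frame_index: int) -> float:
        """Frame time for an index, extrapolated from the uniform cadence if
        the index itself is not part of the track (e.g. a mother track that
        ends just before the onset frame)."""
        for o in self.outlines:
            if o.frame_index == frame_index:
                return o.frame_time
        o0 = self.outlines[0]
        return o0.frame_time + (frame_index - o0.frame_index) * self.frame_interval


def _anchor_frame_index(track: CellTrack, convention: OnsetConvention) -> int:
    if track.anaphase_onset_frame is None:
        raise ConfigurationError("anaphase_onset_frame is not set")
    if convention == "first_elongation":
        return track.anaphase_onset_frame
    if convention == "frame_before":
        return track.anaphase_onset_frame - 1
    raise ConfigurationError(f"unknown onset convention: {convention!r}")


def anchor_times(
    track: CellTrack, convention: OnsetConvention = "first_elongation"
) -> list[tuple[int, float]]:
    """(frame_index, offset_min) for every frame, offset 0 at the anchor."""
    t0 = track.time_of_index(_anchor_frame_index(track, convention))
    return [(o.frame_index, o.frame_time - t0) for o in track.outlines]


def frame_at_offset(
    track: CellTrack,
    offset_min: float,
    convention: OnsetConvention = "first_elongation",
) -> CellOutline:
    """Outline at the nearest frame to ``offset_min`` after the anchor.

    The nearest frame is accepted when within half the frame interval;
    otherwise a :class:`MissingFrameError` names the offset.
    """
    offsets = anchor_times(track, convention)
    diffs = [abs(off - offset_min) for _, off in offsets]
    k = int(np.argmin(diffs))
    if diffs[k] > track.frame_interval / 2 + 1e-9:
        raise MissingFrameError(
            f"no frame within {track.frame_interval / 2:g} min of offset "
            f"{offset_min:+g} min"
        )
    return track.outlines[k]


def _metaphase_reference(
    track: CellTrack, convention: OnsetConvention
) -> CellOutline:
    """Metaphase reference = the frame immediately before first elongation."""
    if track.anaphase_onset_frame is None:
        raise ConfigurationError("anaphase_onset_frame is not set")
    return track.outline_at_index(track.anaphase_onset_frame - 1)


@dataclass
class DivisionEvent:
    """A division linking a mother track to its two daughter tracks.

    The anaphase anchor is shared: daughters' first frames must lie at or
    after the mother's ``anaphase_onset_frame``.
    """

    mother: CellTrack
    daughter_a: CellTrack
    daughter_b: CellTrack
    event_id: str = ""

    def __post_init__(self) -> None:
        onset = self.mother.anaphase_onset_frame
        if onset is None:
            raise ConfigurationError("mother track needs anaphase_onset_frame")
        for d in (self.daughter_a, self.daughter_b):
            if d.anaphase_onset_frame is None:
                d.anaphase_onset_frame = onset
            if d.outlines[0].frame_index < onset:
                raise ConfigurationError(
                    "daughter track starts before the anaphase anchor"
                )

    @property
    def daughters(self) -> tuple[CellTrack, CellTrack]:
        return self.daughter_a, self.daughter_b


@dataclass(frozen=True)
class ShapeChangeStep:
    """One consecutive-frame comparison along a track."""

    offset_min: float  # offset of the later frame
    dissimilarity: float
    area_ratio: float  # later / earlier area
    displacement_um: float  # centroid travel
    orientation_change_deg: float  # folded to [0, 90]


@dataclass
class ExitMetrics:
    """Bundle of per-event mitotic-exit measurements."""

    metaphase_area: float
    area_at_offset: float
    respread_ratio: float
    daughter_area_ratio: float | None
    asymmetric: bool | None
    metaphase_feret: float
    shape_change_series: list[ShapeChangeStep] = field(default_factory=list)
    mother_similarity_series: list[tuple[float, float]] = field(default_factory=list)


# -- operations --------------------------------------------------------------


def respread_ratio(
    event_or_track,
    offset_min: float = 10.0,
    convention: OnsetConvention = "first_elongation",
) -> float:
    """Post-anaphase area / metaphase area.

    For a :class:`DivisionEvent` the post-anaphase area is the area of the
    *union* footprint of the two daughters (logical OR — overlapping regions
    are never double-counted); the metaphase area comes from the mother.
    """
    if isinstance(event_or_track, DivisionEvent):
        ev = event_or_track
        meta = _metaphase_reference(ev.mother, convention)
        da = frame_at_offset(ev.daughter_a, offset_min, convention)
        db = frame_at_offset(ev.daughter_b, offset_min, convention)
        post = polygon_area([da, db])
    else:
        track = event_or_track
        meta = _metaphase_reference(track, convention)
        post = polygon_area(frame_at_offset(track, offset_min, convention))
    return post / meta.area


def shape_change_series(
    track: CellTrack,
    convention: OnsetConvention = "first_elongation",
    pixel_size: float | None = None,
) -> list[ShapeChangeStep]:
    """Consecutive-frame intrinsic shape change along a track.

    Each step aligns frame t+1 onto frame t with area, displacement and
    orientation contributions removed and reports the residual Jaccard
    dissimilarity, together with the raw per-step component series (area
    ratio, centroid displacement in µm, folded orientation change in deg).
    """
    if len(track.outlines) < 2:
        raise InsufficientDataError("shape_change_series needs at least 2 frames")
    offsets = dict(anchor_times(track, convention)) if (
        track.anaphase_onset_frame is not None
    ) else {o.frame_index: o.frame_time for o in track.outlines}
    steps: list[ShapeChangeStep] = []
    for prev, curr in zip(track.outlines[:-1], track.outlines[1:]):
        res = align_intrinsic(prev, curr, ALL_COMPONENTS, pixel_size=pixel_size)
        steps.append(
            ShapeChangeStep(
                offset_min=offsets[curr.frame_index],
                dissimilarity=res.dissimilarity,
                area_ratio=curr.area / prev.area,
                displacement_um=float(
                    np.linalg.norm(curr.centroid - prev.centroid)
                ),
                orientation_change_deg=fold_90(
                    moments_orientation(curr) - moments_orientation(prev)
                ),
            )
        )
    return steps


def _mother_reference(
    event: DivisionEvent, convention: OnsetConvention
) -> tuple[CellOutline, bool]:
    """Mother shape at NEB − 15 min; when NEB is unknown, fall back to 15 min
    before the metaphase reference (returned flag is True)."""
    mother = event.mother
    if mother.neb_frame is not None:
        t_neb = mother.time_of_index(mother.neb_frame)
        target = t_neb - MOTHER_REFERENCE_BEFORE_NEB_MIN
        fallback = False
    else:
        meta = _metaphase_reference(mother, convention)
        target = meta.frame_time - MOTHER_REFERENCE_BEFORE_NEB_MIN
        fallback = True
    times = np.array([o.frame_time for o in mother.outlines])
    k = int(np.argmin(np.abs(times - target)))
    if abs(times[k] - target) > mother.frame_interval / 2 + 1e-9:
        raise MissingFrameError(
            f"no mother frame within {mother.frame_interval / 2:g} min of the "
            f"reference time {target:g} min"
        )
    return mother.outlines[k], fallback


def mother_similarity_series(
    event: DivisionEvent,
    offsets_min: Sequence[float] | None = None,
    convention: OnsetConvention = "first_elongation",
    pixel_size: float | None = None,
    require_neb: bool = True,
) -> list[tuple[float, float]]:
    """Intrinsic Jaccard similarity of the daughters' union footprint to the
    mother reference shape (mother at NEB − 15 min), per post-anaphase
    offset.

    The mother is the alignment reference; the daughter union is the moving
    footprint with area, displacement and orientation contributions removed.
    Offsets where either daughter is missing are skipped.
    """
    if require_neb and event.mother.neb_frame is None:
        raise ConfigurationError(
            "mother track has no neb_frame; pass require_neb=False to use the "
            "15-min-before-metaphase fallback"
        )
    ref, _ = _mother_reference(event, convention)
    if offsets_min is None:
        offsets_min = sorted(
            {off for _, off in anchor_times(event.daughter_a, convention) if off >= 0}
        )
    series: list[tuple[float, float]] = []
    for off in offsets_min:
        try:
            da = frame_at_offset(event.daughter_a, off, convention)
            db = frame_at_offset(event.daughter_b, off, convention)
        except MissingFrameError:
            continue
        res = align_intrinsic(ref, [da, db], ALL_COMPONENTS, pixel_size=pixel_size)
        series.append((off, res.jaccard))
    return series


def mother_similarity(
    event: DivisionEvent,
    offset_min: float = 25.0,
    convention: OnsetConvention = "first_elongation",
    pixel_size: float | None = None,
    require_neb: bool = True,
) -> float:
    """Single-timepoint mother-vs-daughters intrinsic Jaccard similarity."""
    series = mother_similarity_series(
        event, [offset_min], convention, pixel_size, require_neb
    )
    if not series:
        raise MissingFrameError(
            f"daughter frames missing at offset {offset_min:+g} min"
        )
    return series[0][1]


def daughter_area_ratio(
    event: DivisionEvent,
    offset_min: float = 20.0,
    convention: OnsetConvention = "first_elongation",
) -> float:
    """Larger/smaller daughter area at the offset frame (>= 1).

    Raises :class:`MissingFrameError` when either daughter lacks the frame —
    a half-observed division is censored, never scored as infinite ratio.
    """
    a = frame_at_offset(event.daughter_a, offset_min, convention).area
    b = frame_at_offset(event.daughter_b, offset_min, convention).area
    return max(a, b) / min(a, b)


def classify_symmetry(ratio: float, threshold: float = 2.0) -> str:
    """'asymmetric' iff ratio >= threshold (the boundary counts as
    asymmetric), else 'symmetric'."""
    if ratio < 1.0:
        raise ConfigurationError("daughter area ratio must be >= 1")
    return "asymmetric" if ratio >= threshold else "symmetric"


def metaphase_feret(
    track: CellTrack, convention: OnsetConvention = "first_elongation"
) -> float:
    """Feret (maximum caliper) length of the metaphase outline, µm."""
    return feret_length(_metaphase_reference(track, convention))


def exit_metrics(
    event: DivisionEvent,
    respread_offset_min: float = 10.0,
    ratio_offset_min: float = 20.0,
    similarity_offset_min: float = 25.0,
    asymmetry_threshold: float = 2.0,
    convention: OnsetConvention = "first_elongation",
    pixel_size: float | None = None,
    include_series: bool = False,
    include_similarity: bool = True,
    require_neb: bool = True,
) -> ExitMetrics:
    """Compute the standard per-event exit metrics in one pass.

    Metrics whose frames are missing are reported as ``None`` rather than
    raising, so cohort analyses can censor and count exclusions.
    """
    meta = _metaphase_reference(event.mother, convention)
    rr = respread_ratio(event, respread_offset_min, convention)
    try:
        ratio = daughter_area_ratio(event, ratio_offset_min, convention)
        asym = classify_symmetry(ratio, asymmetry_threshold) == "asymmetric"
    except MissingFrameError:
        ratio, asym = None, None
    sim: list[tuple[float, float]] = []
    if include_similarity:
        try:
            sim = [
                (
                    similarity_offset_min,
                    mother_similarity(
                        event,
                        similarity_offset_min,
                        convention,
                        pixel_size,
                        require_neb,
                    ),
                )
            ]
        except MissingFrameError:
            pass
    metrics = ExitMetrics(
        metaphase_area=meta.area,
        area_at_offset=rr * meta.area,
        respread_ratio=rr,
        daughter_area_ratio=ratio,
        asymmetric=asym,
        metaphase_feret=feret_length(meta),
        mother_similarity_series=sim,
    )
    if include_series:
        for d in event.daughters:
            if len(d.outlines) >= 2:
                metrics.shape_change_series.extend(
                    shape_change_series(d, convention, pixel_size)
                )
    return metrics
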