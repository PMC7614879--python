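"""Ground-truth generators emulating time-lapse observations of dividing
cells: footprint series through rounding, division and respreading; x-z
spindle-tilt trajectories; and spheroid time-lapses with dividing cells.

Every phenotype parameter is controllable and every realized value is
recorded in a sidecar manifest, so pipeline measurements can be checked
against generator ground truth without any external data.  Generation is
fully deterministic: each event draws from a counter-based substream keyed
on ``(seed, event_id)``, so cohorts are order-independent and partially
regenerable.

The generator is phenomenological.  Footprints are star-shaped polygons
whose radial profiles interpolate between programmed start and end states;
there is no mechanical model of contractility or adhesion.  The two presets
(``control`` and ``ras_like``) differ in asymmetry probability, shape-memory
fidelity, respreading gain, boundary noise, motility and initial spindle
tilt; their values are motivated by the contrast between unperturbed
epithelial cells and cells with acutely activated Ras-ERK signalling, not
calibrated to any particular dataset.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .errors import ConfigurationError
from .geometry import CellOutline, fold_90, polygon_centroid
from .orientation import SpheroidFrame, SpindleTrack
from .respreading import CellTrack, DivisionEvent

__all__ = [
    "CohortParams",
    "SpindleSimParams",
    "Cohort",
    "generate_shape",
    "generate_division_event",
    "generate_spindle_track",
    "generate_spheroid_timelapse",
    "generate_cohort",
    "PRESETS",
]


# -- parameters --------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Controls for a cohort of synthetic division events.

    Units: areas µm², times minutes, motility µm/frame.  ``asymmetry_prob``
    is the probability that a division is generated asymmetric, with the
    daughter area ratio then drawn from ``asym_ratio_range`` (>= 2);
    symmetric divisions draw their ratio from ``sym_ratio_range`` (in
    [1, 2)).  ``memory_fidelity`` in [0, 1] is the fraction of daughter
    respreading confined to the mother's interphase footprint, and
    ``respread_gain`` the combined-daughter area at +10 min relative to the
    metaphase area.
    """

    n_events: int = 30
    seed: int = 0
    asymmetry_prob: float = 0.03
    asym_ratio_range: tuple[float, float] = (2.0, 4.0)
    sym_ratio_range: tuple[float, float] = (1.0, 1.8)
    memory_fidelity: float = 0.9
    respread_gain: float = 1.6
    shape_noise: float = 0.02
    frame_interval: float = 5.0
    motility: float = 0.3
    interphase_area: float = 1200.0
    rounding_factor: float = 0.45
    mother_irregularity: float = 0.25
    n_boundary_vertices: int = 64

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymmetry_prob <= 1.0:
            raise ConfigurationError("asymmetry_prob must lie in [0, 1]")
        if not 0.0 <= self.memory_fidelity <= 1.0:
            raise ConfigurationError("memory_fidelity must lie in [0, 1]")
        if self.asym_ratio_range[0] < 2.0 or (
            self.asym_ratio_range[0] > self.asym_ratio_range[1]
        ):
            raise ConfigurationError("asym_ratio_range must be ordered and >= 2")
        if not (1.0 <= self.sym_ratio_range[0] <= self.sym_ratio_range[1] < 2.0):
            raise ConfigurationError("sym_ratio_range must lie within [1, 2)")
        if self.respread_gain <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("respread_gain and frame_interval must be > 0")
        if not 0.0 <= self.shape_noise < 0.5:
            raise ConfigurationError("shape_noise must lie in [0, 0.5)")


@dataclass(frozen=True)
class SpindleSimParams:
    """Controls for a synthetic x-z spindle-tilt trajectory.

    ``initial_tilt`` is either a fixed angle in degrees or a (lo, hi)
    uniform range; each frame the tilt relaxes toward 0 by
    ``correction_rate`` (deg/frame, floored at 0) and receives Gaussian
    noise of ``noise_sd`` deg/frame, after which it is folded to [0, 90].
    """

    initial_tilt: float | tuple[float, float] = 20.0
    correction_rate: float = 3.0
    noise_sd: float = 2.0
    n_frames: int = 12
    frame_interval: float = 3.0
    anaphase_onset_frame: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correction_rate < 0 or self.noise_sd < 0:
            raise ConfigurationError("correction_rate and noise_sd must be >= 0")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")


# Timeline of a generated event, in frames of ``frame_interval`` minutes.
MOTHER_REFERENCE_FRAME = 0  # NEB - 15 min
NEB_FRAME = 3
ANAPHASE_ONSET_FRAME = 7
N_DAUGHTER_FRAMES = 7  # offsets 0 .. +30 min at 5-min cadence
RESPREAD_TAU_MIN = 6.0  # saturation time of the respreading area curve
INSIDE_MARGIN = 0.93  # daughters respread slightly inside the mother edge


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(s) for s in stream]])


def _smooth_unit_noise(rng: np.random.Generator, n: int, window: int = 7) -> np.ndarray:
    """Circularly smoothed noise with values in [-1, 1]."""
    u = rng.uniform(-1.0, 1.0, n)
    k = np.hanning(window)
    k /= k.sum()
    s = np.convolve(np.concatenate([u[-window:], u, u[:window]]), k, mode="same")
    s = s[window:-window]
    m = np.max(np.abs(s))
    return s / m if m > 0 else s


def _radial_polygon(center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    n = len(radii)
    ang = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + radii * np.cos(ang), center[1] + radii * np.sin(ang)]
    )


def _radial_area(radii: np.ndarray) -> float:
    """Shoelace area of the star polygon with the given radii on a uniform
    angle grid (closed form: ½ Σ rᵢ rᵢ₊₁ sin Δθ)."""
    n = len(radii)
    return float(0.5 * np.sin(2 * math.pi / n) * np.sum(radii * np.roll(radii, -1)))


def _scale_radii_to_area(radii: np.ndarray, target_area: float) -> np.ndarray:
    a = _radial_area(radii)
    if a <= 0:
        raise ConfigurationError("degenerate radial profile")
    return radii * math.sqrt(target_area / a)


def _radial_resample(geom: Polygon, center: np.ndarray, n: int) -> np.ndarray:
    """Radial profile of a polygon about an interior point: distance to the
    first boundary crossing along n equally spaced rays (so the resampled
    star polygon is contained in the region up to ray discretization)."""
    if geom.geom_type == "MultiPolygon":
        geom = max(geom.geoms, key=lambda g: g.area)
    if not geom.contains(shapely.points(center)):
        c = geom.representative_point()
        center = np.array([c.x, c.y])
    reach = 4.0 * math.sqrt(geom.area) + geom.length
    ang = 2.0 * math.pi * np.arange(n) / n
    radii = np.empty(n)
    ext = geom.exterior
    for i, a in enumerate(ang):
        ray = LineString(
            [center, (center[0] + reach * math.cos(a), center[1] + reach * math.sin(a))]
        )
        hit = ray.intersection(ext)
        if hit.is_empty:
            radii[i] = 1e-6
            continue
        # collect coordinates from whatever geometry the intersection returned
        coords = []
        stack = [hit]
        while stack:
            g = stack.pop()
            if hasattr(g, "geoms"):
                stack.extend(g.geoms)
            else:
                coords.extend(list(g.coords))
        d = np.linalg.norm(np.asarray(coords) - center, axis=1)
        radii[i] = float(d.min())
    return radii


def _halfplane(p0: np.ndarray, direction: np.ndarray, side: float, reach: float) -> Polygon:
    """Large quad covering the halfplane on ``side`` (+1/-1) of the line
    through p0 along ``direction``."""
    d = direction / np.linalg.norm(direction)
    nvec = side * np.array([-d[1], d[0]])
    a = p0 - reach * d
    b = p0 + reach * d
    return Polygon([a, b, b + reach * 2 * nvec, a + reach * 2 * nvec])


def generate_shape(
    n_vertices: int = 64,
    irregularity: float = 0.2,
    seed: int = 0,
    radius: float = 20.0,
    center: Sequence[float] = (0.0, 0.0),
    **outline_kwargs,
) -> CellOutline:
    """Star-shaped polygon from smoothed radial noise around a base radius.

    ``irregularity`` 0 gives a regular n-gon; any value < 1 keeps all radii
    positive, so the polygon is always simple.  Deterministic per seed.
    """
    if n_vertices < 8:
        raise ConfigurationError("n_vertices must be >= 8")
    if not 0.0 <= irregularity < 1.0:
        raise ConfigurationError("irregularity must lie in [0, 1)")
    rng = _rng(seed)
    noise = _smooth_unit_noise(rng, n_vertices) if irregularity > 0 else np.zeros(
        n_vertices
    )
    radii = radius * (1.0 + irregularity * noise)
    verts = _radial_polygon(np.asarray(center, float), radii)
    return CellOutline(vertices=verts, **outline_kwargs)


def _disc_radii(n: int, area: float) -> np.ndarray:
    return _scale_radii_to_area(np.ones(n), area)


def _split_mother(
    mother: Polygon, axis_deg: float, weight_large: float, n: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Split the mother polygon by a line perpendicular to the division axis,
    offset so the two parts carry area fractions (weight_large,
    1 - weight_large); return each part's (center, radial profile)."""
    c = np.array([mother.centroid.x, mother.centroid.y])
    d = np.array([math.cos(math.radians(axis_deg)), math.sin(math.radians(axis_deg))])
    perp = np.array([-d[1], d[0]])
    reach = 4.0 * math.sqrt(mother.area) + mother.length
    lo, hi = -reach / 2, reach / 2

    def large_frac(offset: float) -> float:
        hp = _halfplane(c + offset * d, perp, +1.0, reach)
        return mother.intersection(hp).area / mother.area

    # large_frac decreases monotonically with offset along +d
    sign = 1.0 if large_frac(lo) > large_frac(hi) else -1.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if sign * (large_frac(mid) - weight_large) > 0:
            lo = mid
        else:
            hi = mid
    offset = (lo + hi) / 2
    parts = []
    for side in (+1.0, -1.0):
        piece = mother.intersection(_halfplane(c + offset * d, perp, side, reach))
        if piece.geom_type == "MultiPolygon":
            piece = max(piece.geoms, key=lambda g: g.area)
        pc = np.array([piece.centroid.x, piece.centroid.y])
        parts.append((pc, _radial_resample(piece, pc, n)))
    centers = [p[0] for p in parts]
    radii = [p[1] for p in parts]
    return centers, radii


def generate_division_event(
    params: CohortParams, seed: int | None = None, event_id: int = 0
) -> tuple[DivisionEvent, dict]:
    """One synthetic division event plus its ground-truth record.

    The mother track runs from interphase (NEB − 15 min) through rounding to
    a metaphase disc; the two daughter tracks respread from half-discs to
    programmed target footprints.  The programmed daughter area ratio is
    realized *exactly* at every post-anaphase frame (footprints are rescaled
    to their target areas after noise), and ``memory_fidelity`` blends each
    daughter's target between a region of the mother footprint (fidelity 1)
    and an escaped, displaced random shape (fidelity 0).
    """
    seed = params.seed if seed is None else seed
    rng = _rng(seed, event_id)
    n = params.n_boundary_vertices
    dt = params.frame_interval

    a0 = params.interphase_area
    a_meta = params.rounding_factor * a0
    gain = params.respread_gain
    sat10 = 1.0 - math.exp(-10.0 / RESPREAD_TAU_MIN)
    a_inf = a_meta + (gain - 1.0) * a_meta / sat10
    if params.memory_fidelity >= 1.0 and a_inf > a0:
        raise ConfigurationError(
            "infeasible parameters: with memory_fidelity 1 the combined "
            f"daughter area ({a_inf:.0f} µm²) cannot exceed the mother "
            f"footprint ({a0:.0f} µm²); lower respread_gain or rounding_factor"
        )

    asymmetric = bool(rng.random() < params.asymmetry_prob)
    lo, hi = params.asym_ratio_range if asymmetric else params.sym_ratio_range
    ratio = float(rng.uniform(lo, hi))
    w_large = ratio / (1.0 + ratio)
    axis_deg = float(rng.uniform(0.0, 180.0))

    # mother footprint (interphase) and its rounding to a metaphase disc
    base_noise = _smooth_unit_noise(rng, n)
    mother_radii = _scale_radii_to_area(
        1.0 + params.mother_irregularity * base_noise, a0
    )
    mother_center = np.zeros(2)
    disc_radii = _disc_radii(n, a_meta)

    def outline(center, radii, frame_index, cell_id):
        return CellOutline(
            vertices=_radial_polygon(center, radii),
            frame_time=frame_index * dt,
            cell_id=cell_id,
            frame_index=frame_index,
        )

    drift = params.motility * rng.standard_normal((ANAPHASE_ONSET_FRAME + N_DAUGHTER_FRAMES, 2))
    drift[0] = 0.0
    pos = np.cumsum(drift, axis=0)

    mid = f"{event_id}m"
    mother_outlines = []
    for f in range(ANAPHASE_ONSET_FRAME):
        if f <= NEB_FRAME:
            radii, area = mother_radii, a0
        else:  # rounding: blend footprint toward the metaphase disc
            q = (f - NEB_FRAME) / (ANAPHASE_ONSET_FRAME - 1 - NEB_FRAME)
            q = min(q, 1.0)
            radii = (1 - q) * mother_radii + q * disc_radii
            area = (1 - q) * a0 + q * a_meta
        radii = _scale_radii_to_area(radii, area)
        mother_outlines.append(outline(mother_center + pos[f], radii, f, mid))
    mother = CellTrack(
        outlines=mother_outlines,
        frame_interval=dt,
        neb_frame=NEB_FRAME,
        anaphase_onset_frame=ANAPHASE_ONSET_FRAME,
    )

    # daughter targets: inside-mother split vs escaped shapes, blended by
    # memory fidelity (radial blend keeps every intermediate star-shaped)
    mother_poly = Polygon(_radial_polygon(mother_center, mother_radii))
    in_centers, in_radii = _split_mother(mother_poly, axis_deg, w_large, n)
    in_radii = [r * INSIDE_MARGIN for r in in_radii]

    d_axis = np.array(
        [math.cos(math.radians(axis_deg)), math.sin(math.radians(axis_deg))]
    )
    esc_dist = 0.9 * math.sqrt(a0)
    esc_centers = [
        mother_center + esc_dist * d_axis,
        mother_center - esc_dist * d_axis,
    ]
    esc_radii = [
        1.0 + 0.3 * _smooth_unit_noise(_rng(seed, event_id, 10 + k), n)
        for k in range(2)
    ]

    f_mem = params.memory_fidelity
    weights = (w_large, 1.0 - w_large)
    targets = []
    for k in range(2):
        centre = f_mem * in_centers[k] + (1 - f_mem) * esc_centers[k]
        prof_in = in_radii[k]
        prof_esc = _scale_radii_to_area(esc_radii[k], _radial_area(prof_in))
        targets.append((centre, f_mem * prof_in + (1 - f_mem) * prof_esc))

    # metaphase disc split into two half-disc starting profiles
    disc_poly = Polygon(_radial_polygon(mother_center, disc_radii))
    half_centers, half_radii = _split_mother(disc_poly, axis_deg, w_large, n)

    daughter_outlines: list[list[CellOutline]] = [[], []]
    meas_areas_by_offset: dict[float, list[float]] = {}
    for j in range(N_DAUGHTER_FRAMES):
        t = j * dt
        a_comb = a_meta + (a_inf - a_meta) * (1.0 - math.exp(-t / RESPREAD_TAU_MIN))
        q = (a_comb - a_meta) / (a_inf - a_meta)
        verts_pair = []
        for k in range(2):
            centre = (1 - q) * half_centers[k] + q * targets[k][0]
            radii = (1 - q) * half_radii[k] + q * targets[k][1]
            if params.shape_noise > 0:
                pert = _smooth_unit_noise(_rng(seed, event_id, 100 + k, j), n)
                radii = radii * (1.0 + params.shape_noise * pert)
            area_k = weights[k] * a_comb
            radii = _scale_radii_to_area(radii, area_k)
            verts_pair.append(_radial_polygon(centre, radii))
            meas_areas_by_offset.setdefault(t, []).append(area_k)
        # daughters must not overlap (their union area is a measured
        # quantity): separate along the division axis until disjoint;
        # translation preserves the exact per-daughter areas
        for _ in range(12):
            inter = Polygon(verts_pair[0]).intersection(Polygon(verts_pair[1]))
            if inter.area <= 1e-9 * a_comb:
                break
            pieces = getattr(inter, "geoms", [inter])
            proj = np.concatenate(
                [np.asarray(g.exterior.coords) @ d_axis for g in pieces]
            )
            shift = (proj.max() - proj.min()) / 2.0 + 0.05
            verts_pair[0] = verts_pair[0] + shift * d_axis
            verts_pair[1] = verts_pair[1] - shift * d_axis
        frame_index = ANAPHASE_ONSET_FRAME + j
        for k in range(2):
            # footprint-anchored respreading: post-anaphase drift scales
            # with (1 - fidelity) so full shape memory stays in place
            daughter_outlines[k].append(
                CellOutline(
                    vertices=verts_pair[k] + (1.0 - f_mem) * pos[frame_index - 1],
                    frame_time=frame_index * dt,
                    cell_id=f"{event_id}d{'ab'[k]}",
                    frame_index=frame_index,
                )
            )
    daughters = [
        CellTrack(
            outlines=outs,
            frame_interval=dt,
            anaphase_onset_frame=ANAPHASE_ONSET_FRAME,
        )
        for outs in daughter_outlines
    ]

    event = DivisionEvent(
        mother=mother,
        daughter_a=daughters[0],
        daughter_b=daughters[1],
        event_id=str(event_id),
    )
    truth = {
        "event_id": event_id,
        "asymmetric": asymmetric,
        "daughter_area_ratio": ratio,
        "memory_fidelity": f_mem,
        "respread_gain": gain,
        "division_axis_deg": axis_deg,
        "interphase_area_um2": a0,
        "metaphase_area_um2": a_meta,
        "combined_area_at_10min_um2": a_meta * gain,
        "daughter_areas_um2": {
            f"{off:g}": [round(a, 6) for a in areas]
            for off, areas in sorted(meas_areas_by_offset.items())
        },
    }
    return event, truth


def generate_spindle_track(
    params: SpindleSimParams, seed: int | None = None, track_id: str = ""
) -> tuple[SpindleTrack, dict]:
    """Synthetic spindle-tilt trajectory plus bookkept ground truth.

    The folded-angle process is θₜ₊₁ = fold₉₀(max(0, θₜ − correction_rate)
    + noise), realized as pole coordinates at a fixed 10 µm pole-pole
    distance, so the pipeline's ``spindle_angle`` recovers each recorded
    angle exactly (the construction is its inverse).
    """
    seed = params.seed if seed is None else seed
    rng = _rng(seed, 7)
    if isinstance(params.initial_tilt, (tuple, list)):
        theta = float(rng.uniform(*params.initial_tilt))
    else:
        theta = float(params.initial_tilt)
    theta = fold_90(theta)
    angles = [theta]
    for _ in range(params.n_frames - 1):
        nxt = max(0.0, angles[-1] - params.correction_rate)
        if params.noise_sd > 0:
            nxt += float(rng.normal(0.0, params.noise_sd))
        angles.append(fold_90(nxt))
    half = 5.0
    centre = np.array([0.0, 8.0])
    frames = []
    for th in angles:
        d = half * np.array([math.cos(math.radians(th)), math.sin(math.radians(th))])
        frames.append((tuple(centre - d), tuple(centre + d)))
    track = SpindleTrack(
        frames=frames,
        frame_interval=params.frame_interval,
        anaphase_onset_frame=params.anaphase_onset_frame,
        track_id=track_id,
    )
    increments = [abs(b - a) for a, b in zip(angles[:-1], angles[1:])]
    truth = {
        "angles_deg": angles,
        "cumulative_change_deg": float(sum(increments)),
        "increments_deg": increments,
        "anaphase_onset_frame": params.anaphase_onset_frame,
        "frame_interval_min": params.frame_interval,
    }
    return track, truth


def generate_spheroid_timelapse(
    circularity_drift: float = -0.01,
    growth_rate: float = 0.01,
    division_angle: float | tuple[float, float] = (0.0, 90.0),
    n_frames: int = 10,
    seed: int = 0,
    frame_interval_min: float = 120.0,
    base_radius: float = 60.0,
    n_vertices: int = 128,
) -> tuple[list[SpheroidFrame], dict]:
    """Spheroid outline series with one dividing cell per frame.

    The outline is a three-lobed perturbation of a circle whose lobe
    amplitude grows at a rate set by ``-circularity_drift`` (so negative
    drift gives a strictly decreasing circularity series) while the area
    grows by ``growth_rate`` per frame (exact, by rescaling).  Each frame
    places a division with its chromosome axis at a programmed angle to the
    measured centroid-periphery axis, so the pipeline recovers the
    programmed angles exactly.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = _rng(seed, 3)
    lobe_rate = max(0.0, -circularity_drift)
    base_area = math.pi * base_radius**2
    ang = 2.0 * math.pi * np.arange(n_vertices) / n_vertices
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    frames: list[SpheroidFrame] = []
    truth_rows = []
    for t in range(n_frames):
        amp = lobe_rate * t
        area = base_area * (1.0 + growth_rate) ** t
        radii = _scale_radii_to_area(1.0 + amp * np.cos(3 * ang + phase), area)
        verts = _radial_polygon(np.zeros(2), radii)
        outline = CellOutline(
            vertices=verts, frame_time=t * frame_interval_min, frame_index=t
        )
        centroid = polygon_centroid(outline)
        psi = float(rng.uniform(0.0, 360.0))
        if isinstance(division_angle, (tuple, list)):
            delta = float(rng.uniform(*division_angle))
        else:
            delta = float(division_angle)
        r_here = 0.6 * float(np.interp(math.radians(psi) % (2 * math.pi), ang, radii))
        dp = centroid + r_here * np.array(
            [math.cos(math.radians(psi)), math.sin(math.radians(psi))]
        )
        chrom_dir = np.array(
            [
                math.cos(math.radians(psi + delta)),
                math.sin(math.radians(psi + delta)),
            ]
        )
        axis = (tuple(dp - 4.0 * chrom_dir), tuple(dp + 4.0 * chrom_dir))
        frames.append(
            SpheroidFrame(outline=outline, division_point=tuple(dp), chromosome_axis=axis)
        )
        truth_rows.append(
            {
                "frame": t,
                "area_um2": area,
                "division_angle_deg": fold_90(delta),
                "radial_axis_deg": psi,
            }
        )
    truth = {
        "circularity_drift": circularity_drift,
        "growth_rate": growth_rate,
        "frames": truth_rows,
    }
    return frames, truth


# -- cohorts and presets -----------------------------------------------------

PRESETS: dict[str, dict] = {
    # Unperturbed epithelial cells: rare asymmetry, high shape memory,
    # moderate respreading, small initial spindle tilt, quick correction.
    "control": {
        "cohort": CohortParams(
            asymmetry_prob=0.03,
            memory_fidelity=0.9,
            respread_gain=1.5,
            shape_noise=0.02,
            motility=0.3,
        ),
        "spindle": SpindleSimParams(
            initial_tilt=(0.0, 25.0), correction_rate=4.0, noise_sd=2.0
        ),
    },
    # Acute oncogenic-signalling phenotype: frequent asymmetric respreading,
    # poor shape memory, faster spreading, noisier boundaries, larger and
    # poorly corrected spindle tilt.
    "ras_like": {
        "cohort": CohortParams(
            asymmetry_prob=0.37,
            memory_fidelity=0.3,
            respread_gain=1.8,
            shape_noise=0.06,
            motility=1.0,
        ),
        "spindle": SpindleSimParams(
            initial_tilt=(10.0, 70.0), correction_rate=1.0, noise_sd=4.0
        ),
    },
}


@dataclass
class Cohort:
    """A reproducible set of division events and spindle tracks with the
    ground-truth manifest that generated them."""

    events: list[DivisionEvent]
    spindle_tracks: list[SpindleTrack]
    manifest: dict

    def __len__(self) -> int:
        return len(self.events)


def generate_cohort(
    preset: str | CohortParams,
    n: int | None = None,
    seed: int | None = None,
    spindle_params: SpindleSimParams | None = None,
) -> Cohort:
    """Generate ``n`` division events (plus matched spindle tracks) from a
    preset name or explicit :class:`CohortParams`.

    The manifest records the parameters and every ground-truth value;
    identical (preset, n, seed) inputs yield byte-identical manifests.
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ConfigurationError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        params: CohortParams = PRESETS[preset]["cohort"]
        spindle_params = spindle_params or PRESETS[preset]["spindle"]
        preset_name = preset
    else:
        params = preset
        spindle_params = spindle_params or SpindleSimParams()
        preset_name = "custom"
    n = params.n_events if n is None else n
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    seed = params.seed if seed is None else seed

    events, tracks, truths = [], [], []
    for event_id in range(n):
        ev, truth = generate_division_event(params, seed=seed, event_id=event_id)
        sp_params = SpindleSimParams(
            **{**asdict(spindle_params), "seed": 0}
        )
        sp, sp_truth = generate_spindle_track(
            sp_params, seed=_derived_seed(seed, event_id), track_id=str(event_id)
        )
        truth["spindle"] = sp_truth
        events.append(ev)
        tracks.append(sp)
        truths.append(truth)
    manifest = {
        "preset": preset_name,
        "seed": seed,
        "n_events": n,
        "params": asdict(params),
        "spindle_params": asdict(spindle_params),
        "events": truths,
    }
    return Cohort(events=events, spindle_tracks=tracks, manifest=manifest)


def _derived_seed(seed: int, event_id: int) -> int:
    """Stable 31-bit sub-seed for per-event spindle streams."""
    return int(np.random.default_rng([seed, event_id, 99]).integers(0, 2**31 - 1))
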