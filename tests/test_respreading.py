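"""Event-anchored mitotic-exit metrics."""

import math

import numpy as np
import pytest

import mitoshape as ms
from mitoshape.respreading import CellTrack, shape_change_series

from conftest import regular_polygon, star_polygon


def scaled_disc(area: float, center=(0.0, 0.0), n=64, **kw) -> ms.CellOutline:
    r = math.sqrt(area / math.pi)
    # exact-area correction for the n-gon
    r *= math.sqrt(2 * math.pi / (n * math.sin(2 * math.pi / n)))
    ang = 2 * math.pi * np.arange(n) / n
    verts = np.column_stack(
        [center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)]
    )
    return ms.CellOutline(verts, **kw)


def make_track(areas, frame_interval=5.0, onset=None, neb=None, centers=None):
    outlines = [
        scaled_disc(
            a,
            center=(0, 0) if centers is None else centers[i],
            frame_time=i * frame_interval,
            frame_index=i,
        )
        for i, a in enumerate(areas)
    ]
    return CellTrack(
        outlines=outlines,
        frame_interval=frame_interval,
        anaphase_onset_frame=onset,
        neb_frame=neb,
    )


class TestAnchoring:
    def test_offsets_zero_at_onset(self):
        track = make_track([400.0] * 10, onset=6)
        offsets = dict(ms.anchor_times(track))
        assert offsets[6] == 0.0
        assert offsets[8] == 10.0

    def test_plus_ten_resolves_to_frame_eight(self):
        track = make_track([400.0] * 10, onset=6)
        assert ms.frame_at_offset(track, 10.0).frame_index == 8

    def test_nearest_frame_rounding(self):
        track = make_track([400.0] * 10, onset=6)
        assert ms.frame_at_offset(track, 12.0).frame_index == 8  # nearest +10

    def test_offset_beyond_track_raises(self):
        track = make_track([400.0] * 5, onset=1)  # ends at +15
        with pytest.raises(ms.MissingFrameError):
            ms.frame_at_offset(track, 20.0)

    def test_frame_before_convention_shifts_anchor(self):
        track = make_track([400.0] * 10, onset=6)
        offsets = dict(ms.anchor_times(track, convention="frame_before"))
        assert offsets[5] == 0.0

    def test_missing_onset_is_configuration_error(self):
        track = make_track([400.0] * 4)
        with pytest.raises(ms.ConfigurationError):
            ms.anchor_times(track)


class TestTrackValidation:
    def test_non_uniform_spacing_rejected(self):
        outlines = [
            scaled_disc(100.0, frame_time=t, frame_index=i)
            for i, t in enumerate([0.0, 5.0, 11.0])
        ]
        with pytest.raises(ms.ConfigurationError):
            CellTrack(outlines=outlines, frame_interval=5.0)

    def test_decreasing_times_rejected(self):
        outlines = [
            scaled_disc(100.0, frame_time=t, frame_index=i)
            for i, t in enumerate([0.0, 5.0, 4.0])
        ]
        with pytest.raises(ms.ConfigurationError):
            CellTrack(outlines=outlines, frame_interval=5.0)


class TestRespreadRatio:
    def test_arithmetic(self):
        # metaphase 400 at frame 5 (onset 6), 600 at +10 (frame 8)
        areas = [500, 500, 500, 500, 500, 400, 450, 520, 600, 640]
        track = make_track(areas, onset=6)
        assert ms.respread_ratio(track) == pytest.approx(1.5, rel=1e-6)

    def test_constant_track_is_unity(self):
        track = make_track([400.0] * 10, onset=6)
        assert ms.respread_ratio(track) == pytest.approx(1.0, rel=1e-9)

    def test_event_uses_daughter_union(self):
        """Combined daughter area is the union footprint, not the sum."""
        ev, truth = ms.generate_division_event(
            ms.CohortParams(respread_gain=1.8, shape_noise=0.0), seed=4, event_id=0
        )
        assert ms.respread_ratio(ev) == pytest.approx(1.8, rel=0.02)

    def test_missing_frames_raise(self):
        track = make_track([400.0] * 3, onset=2)
        with pytest.raises(ms.MissingFrameError):
            ms.respread_ratio(track, offset_min=10.0)


class TestShapeChangeSeries:
    def test_identical_outlines_zero_dissimilarity(self):
        track = make_track([400.0] * 4, onset=1)
        steps = shape_change_series(track)
        assert all(s.dissimilarity == pytest.approx(0.0, abs=0.01) for s in steps)

    def test_similarity_transformed_track_is_flat(self):
        """Frames built by rigid+scaled transforms score <= 0.02 per step,
        and the raw component series recover the programmed transforms."""
        base = star_polygon(17, irregularity=0.3)
        outlines = []
        for i in range(4):
            o = base.transformed(
                scale=1.1**i, rotation_deg=15.0 * i, translation=(3.0 * i, 0.0)
            )
            outlines.append(
                ms.CellOutline(o.vertices, frame_time=5.0 * i, frame_index=i)
            )
        track = CellTrack(outlines=outlines, frame_interval=5.0, anaphase_onset_frame=0)
        steps = shape_change_series(track)
        for s in steps:
            assert s.dissimilarity <= 0.02
            assert s.area_ratio == pytest.approx(1.1**2, rel=1e-6)
            assert s.orientation_change_deg == pytest.approx(15.0, abs=0.5)
        assert steps[0].displacement_um == pytest.approx(3.0, abs=0.3)

    def test_growing_perturbation_gives_increasing_series(self):
        """Per-step boundary perturbations of growing magnitude produce a
        strictly increasing dissimilarity series."""
        rng = np.random.default_rng(0)
        n = 48
        ang = 2 * math.pi * np.arange(n) / n
        noise = rng.uniform(-1, 1, n)
        outlines = []
        base_r = 20.0
        for i, mag in enumerate([0.0, 0.02, 0.08, 0.2]):
            radii = base_r * (1.0 + mag * noise)
            verts = np.column_stack([radii * np.cos(ang), radii * np.sin(ang)])
            outlines.append(ms.CellOutline(verts, frame_time=5.0 * i, frame_index=i))
        track = CellTrack(outlines=outlines, frame_interval=5.0, anaphase_onset_frame=0)
        diss = [s.dissimilarity for s in shape_change_series(track)]
        assert diss[0] < diss[1] < diss[2]

    def test_needs_two_frames(self):
        track = make_track([400.0], onset=0)
        with pytest.raises(ms.InsufficientDataError):
            shape_change_series(track)


class TestDaughterSymmetry:
    @pytest.mark.parametrize(
        "areas,ratio,label",
        [
            ((200.0, 100.0), 2.0, "asymmetric"),  # boundary counts asymmetric
            ((150.0, 100.0), 1.5, "symmetric"),
            ((100.0, 100.0), 1.0, "symmetric"),
        ],
    )
    def test_ratio_and_threshold(self, areas, ratio, label):
        mother = make_track([300.0] * 6, onset=5, neb=1)
        daughters = [
            CellTrack(
                outlines=[
                    scaled_disc(a, frame_time=(5 + j) * 5.0, frame_index=5 + j)
                    for j in range(5)
                ],
                frame_interval=5.0,
                anaphase_onset_frame=5,
            )
            for a in areas
        ]
        ev = ms.DivisionEvent(mother=mother, daughter_a=daughters[0], daughter_b=daughters[1])
        r = ms.daughter_area_ratio(ev)
        assert r == pytest.approx(ratio, rel=1e-6)
        assert ms.classify_symmetry(r) == label

    def test_label_order_invariance(self):
        mother = make_track([300.0] * 6, onset=5)
        a = CellTrack(
            outlines=[
                scaled_disc(120.0, frame_time=(5 + j) * 5.0, frame_index=5 + j)
                for j in range(5)
            ],
            frame_interval=5.0,
        )
        b = CellTrack(
            outlines=[
                scaled_disc(310.0, frame_time=(5 + j) * 5.0, frame_index=5 + j)
                for j in range(5)
            ],
            frame_interval=5.0,
        )
        ev1 = ms.DivisionEvent(mother=mother, daughter_a=a, daughter_b=b)
        ev2 = ms.DivisionEvent(mother=mother, daughter_a=b, daughter_b=a)
        assert ms.daughter_area_ratio(ev1) == ms.daughter_area_ratio(ev2) >= 1.0

    def test_missing_daughter_raises_not_infinity(self):
        mother = make_track([300.0] * 6, onset=5)
        short = CellTrack(
            outlines=[scaled_disc(100.0, frame_time=25.0, frame_index=5)],
            frame_interval=5.0,
        )
        full = CellTrack(
            outlines=[
                scaled_disc(100.0, frame_time=(5 + j) * 5.0, frame_index=5 + j)
                for j in range(5)
            ],
            frame_interval=5.0,
        )
        ev = ms.DivisionEvent(mother=mother, daughter_a=short, daughter_b=full)
        with pytest.raises(ms.MissingFrameError):
            ms.daughter_area_ratio(ev, offset_min=20.0)


class TestMetaphaseFeret:
    def test_circle_diameter(self):
        areas = [400.0] * 7
        outlines = [
            regular_polygon(128, radius=9.0, center=(0, 0)) for _ in areas
        ]
        outlines = [
            ms.CellOutline(o.vertices, frame_time=i * 5.0, frame_index=i)
            for i, o in enumerate(outlines)
        ]
        track = CellTrack(outlines=outlines, frame_interval=5.0, anaphase_onset_frame=6)
        assert ms.metaphase_feret(track) == pytest.approx(18.0, abs=0.2)

    def test_rectangle_hull_caliper(self):
        rect = ms.CellOutline(
            np.array([[0.0, 0.0], [3, 0], [3, 4], [0, 4]]), frame_time=0.0, frame_index=0
        )
        rect2 = ms.CellOutline(rect.vertices, frame_time=5.0, frame_index=1)
        track = CellTrack(outlines=[rect, rect2], frame_interval=5.0, anaphase_onset_frame=1)
        assert ms.metaphase_feret(track) == pytest.approx(5.0)

    def test_ellipse_major_axis(self):
        t = np.linspace(0, 2 * math.pi, 128, endpoint=False)
        verts = np.column_stack([10.0 * np.cos(t), 6.0 * np.sin(t)])
        o1 = ms.CellOutline(verts, frame_time=0.0, frame_index=0)
        o2 = ms.CellOutline(verts, frame_time=5.0, frame_index=1)
        track = CellTrack(outlines=[o1, o2], frame_interval=5.0, anaphase_onset_frame=1)
        assert ms.metaphase_feret(track) == pytest.approx(20.0, abs=0.2)


class TestMotherSimilarity:
    def _tiling_event(self):
        """Daughters jointly tile exactly the mother footprint."""
        rect = np.array([[0.0, 0.0], [8, 0], [8, 4], [0, 4]])
        left = np.array([[0.0, 0.0], [4, 0], [4, 4], [0, 4]])
        right = np.array([[4.0, 0.0], [8, 0], [8, 4], [4, 4]])
        mother_outlines = [
            ms.CellOutline(rect, frame_time=i * 5.0, frame_index=i) for i in range(8)
        ]
        mother = CellTrack(
            outlines=mother_outlines, frame_interval=5.0, neb_frame=3,
            anaphase_onset_frame=7,
        )
        mk = lambda v: CellTrack(
            outlines=[
                ms.CellOutline(v, frame_time=(7 + j) * 5.0, frame_index=7 + j)
                for j in range(7)
            ],
            frame_interval=5.0,
            anaphase_onset_frame=7,
        )
        return ms.DivisionEvent(mother=mother, daughter_a=mk(left), daughter_b=mk(right))

    def test_tiling_daughters_score_near_one(self):
        ev = self._tiling_event()
        assert ms.mother_similarity(ev, offset_min=25.0) >= 0.98

    def test_series_offsets_are_post_anaphase(self):
        ev = self._tiling_event()
        series = ms.mother_similarity_series(ev)
        assert [off for off, _ in series] == [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0]

    def test_escaped_daughters_score_matches_polygon_oracle(self):
        """Daughters far from the mother shape score the same value as the
        two polygons compared directly (single-shape alignment)."""
        ev = self._tiling_event()
        tri = np.array([[20.0, 0.0], [40.0, 0.0], [20.0, 15.0]])
        esc = CellTrack(
            outlines=[
                ms.CellOutline(tri + 2 * j, frame_time=(7 + j) * 5.0, frame_index=7 + j)
                for j in range(7)
            ],
            frame_interval=5.0,
            anaphase_onset_frame=7,
        )
        thin = np.array([[60.0, 0.0], [61.0, 0.0], [61.0, 1.0], [60.0, 1.0]])
        tiny = CellTrack(
            outlines=[
                ms.CellOutline(thin, frame_time=(7 + j) * 5.0, frame_index=7 + j)
                for j in range(7)
            ],
            frame_interval=5.0,
            anaphase_onset_frame=7,
        )
        ev_escaped = ms.DivisionEvent(
            mother=ev.mother, daughter_a=esc, daughter_b=tiny
        )
        sim = ms.mother_similarity(ev_escaped, offset_min=25.0)
        tiling = ms.mother_similarity(ev, offset_min=25.0)
        assert sim < tiling - 0.1

    def test_memory_fidelity_ordering(self):
        """Mean mother similarity is ordered by programmed shape-memory
        fidelity."""
        means = []
        for f in (0.2, 1.0):
            sims = [
                ms.mother_similarity(
                    ms.generate_division_event(
                        ms.CohortParams(memory_fidelity=f), seed=6, event_id=i
                    )[0]
                )
                for i in range(3)
            ]
            means.append(np.mean(sims))
        assert means[0] < means[1]

    def test_missing_neb_requires_explicit_fallback(self):
        ev = self._tiling_event()
        ev.mother.neb_frame = None
        with pytest.raises(ms.ConfigurationError):
            ms.mother_similarity_series(ev)
        # explicit opt-in uses 15 min before the metaphase reference
        series = ms.mother_similarity_series(ev, require_neb=False)
        assert len(series) > 0
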