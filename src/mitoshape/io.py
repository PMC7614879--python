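"""Readers and writers for the interchange formats.

Dialects
--------
Outline table (CSV)
    columns ``cell_id, frame_index, frame_time_min, vertex_index, x_um,
    y_um``; one row per vertex, vertices ordered by ``vertex_index``.
Outline table (JSON)
    ``{"cells": {cell_id: [{"frame_index": .., "frame_time_min": ..,
    "vertices": [[x, y], ...]}, ...]}}``.
Event table (CSV)
    columns ``event_id, mother_id, daughter_a_id, daughter_b_id, neb_frame,
    anaphase_onset_frame``.
Spindle table (CSV)
    columns ``track_id, frame_index, time_min, p1x, p1z, p2x, p2z,
    anaphase_onset_flag``.
Masks
    multi-page TIFF (one page per frame) with pixel size and per-page
    origin in a JSON sidecar (``<file>.json``).

All coordinates are micrometres and minutes after import.  The vertical
axis convention of outline sources must be declared: ``y_convention="math"``
(y up, the package's internal convention) or ``"image"`` (y down, flipped
on import).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidGeometryError, LoadError
from .geometry import BinaryMask, CellOutline
from .orientation import SpindleTrack
from .respreading import CellTrack, DivisionEvent

__all__ = [
    "read_outlines",
    "write_outlines",
    "read_events",
    "write_events",
    "build_events",
    "read_spindles",
    "write_spindles",
    "read_masks",
    "write_masks",
    "tidy_measurements",
]

OUTLINE_COLUMNS = ["cell_id", "frame_index", "frame_time_min", "vertex_index", "x_um", "y_um"]
EVENT_COLUMNS = [
    "event_id",
    "mother_id",
    "daughter_a_id",
    "daughter_b_id",
    "neb_frame",
    "anaphase_onset_frame",
]
SPINDLE_COLUMNS = [
    "track_id",
    "frame_index",
    "time_min",
    "p1x",
    "p1z",
    "p2x",
    "p2z",
    "anaphase_onset_flag",
]


def _check_y_convention(y_convention: str) -> float:
    if y_convention == "math":
        return 1.0
    if y_convention == "image":
        return -1.0
    raise LoadError(f"unknown y convention {y_convention!r}; use 'math' or 'image'")


def read_outlines(path, y_convention: str = "math") -> dict[str, list[CellOutline]]:
    """Load an outline table (CSV or JSON by extension) into per-cell,
    time-ordered outline lists.  Malformed rows raise :class:`LoadError`
    naming the cell and the offending line."""
    ysign = _check_y_convention(y_convention)
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_outlines_json(path, ysign)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in OUTLINE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    out: dict[str, list[CellOutline]] = {}
    for (cell_id, frame_index), grp in df.groupby(["cell_id", "frame_index"], sort=True):
        grp = grp.sort_values("vertex_index")
        verts = grp[["x_um", "y_um"]].to_numpy(float)
        verts[:, 1] *= ysign
        first_line = int(grp.index.min()) + 2  # header + 1-based
        try:
            outline = CellOutline(
                vertices=verts,
                frame_time=float(grp["frame_time_min"].iloc[0]),
                cell_id=str(cell_id),
                frame_index=int(frame_index),
            )
        except InvalidGeometryError as exc:
            raise LoadError(
                f"{path}:{first_line}: invalid outline for cell "
                f"{cell_id!r} frame {frame_index}: {exc}"
            ) from exc
        out.setdefault(str(cell_id), []).append(outline)
    for outlines in out.values():
        outlines.sort(key=lambda o: o.frame_index)
    return out


def _read_outlines_json(path: Path, ysign: float) -> dict[str, list[CellOutline]]:
    try:
        data = json.loads(Path(path).read_text())
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"{path}: cannot parse JSON ({exc})") from exc
    cells = data.get("cells")
    if not isinstance(cells, dict):
        raise LoadError(f"{path}: expected a top-level 'cells' mapping")
    out: dict[str, list[CellOutline]] = {}
    for cell_id, frames in cells.items():
        for rec in frames:
            verts = np.asarray(rec["vertices"], float)
            verts[:, 1] *= ysign
            try:
                outline = CellOutline(
                    vertices=verts,
                    frame_time=float(rec.get("frame_time_min", 0.0)),
                    cell_id=str(cell_id),
                    frame_index=int(rec.get("frame_index", 0)),
                )
            except InvalidGeometryError as exc:
                raise LoadError(
                    f"{path}: invalid outline for cell {cell_id!r} frame "
                    f"{rec.get('frame_index')}: {exc}"
                ) from exc
            out.setdefault(str(cell_id), []).append(outline)
    for outlines in out.values():
        outlines.sort(key=lambda o: o.frame_index)
    return out


def write_outlines(outlines_by_cell: Mapping[str, Sequence[CellOutline]], path) -> None:
    """Write per-cell outlines as the CSV dialect (math y convention)."""
    rows = []
    for cell_id, outlines in outlines_by_cell.items():
        for o in outlines:
            for k, (x, y) in enumerate(o.vertices):
                rows.append((cell_id, o.frame_index, o.frame_time, k, x, y))
    pd.DataFrame(rows, columns=OUTLINE_COLUMNS).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Load an event table; returns a validated DataFrame."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    return df


def write_events(events: Iterable[DivisionEvent], path) -> None:
    rows = []
    for ev in events:
        rows.append(
            (
                ev.event_id,
                ev.mother.outlines[0].cell_id,
                ev.daughter_a.outlines[0].cell_id,
                ev.daughter_b.outlines[0].cell_id,
                ev.mother.neb_frame,
                ev.mother.anaphase_onset_frame,
            )
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def build_events(
    outlines_by_cell: Mapping[str, Sequence[CellOutline]],
    event_table: pd.DataFrame,
    frame_interval: float = 5.0,
) -> list[DivisionEvent]:
    """Assemble :class:`DivisionEvent` objects from loaded outlines and an
    event table (mother → daughter links plus timing anchors)."""
    events = []
    for _, row in event_table.iterrows():
        tracks = {}
        for role in ("mother_id", "daughter_a_id", "daughter_b_id"):
            cid = str(row[role])
            if cid not in outlines_by_cell:
                raise LoadError(f"event {row['event_id']}: unknown cell id {cid!r}")
            tracks[role] = list(outlines_by_cell[cid])
        neb = row["neb_frame"]
        onset = int(row["anaphase_onset_frame"])
        mother = CellTrack(
            outlines=tracks["mother_id"],
            frame_interval=frame_interval,
            neb_frame=None if pd.isna(neb) else int(neb),
            anaphase_onset_frame=onset,
        )
        events.append(
            DivisionEvent(
                mother=mother,
                daughter_a=CellTrack(
                    outlines=tracks["daughter_a_id"],
                    frame_interval=frame_interval,
                    anaphase_onset_frame=onset,
                ),
                daughter_b=CellTrack(
                    outlines=tracks["daughter_b_id"],
                    frame_interval=frame_interval,
                    anaphase_onset_frame=onset,
                ),
                event_id=str(row["event_id"]),
            )
        )
    return events


def read_spindles(path) -> list[SpindleTrack]:
    """Load spindle pole tracks from the spindle CSV dialect."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise LoadError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in SPINDLE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    tracks = []
    for track_id, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame_index")
        times = grp["time_min"].to_numpy(float)
        if len(times) > 1:
            dt = np.diff(times)
            interval = float(dt[0])
            if np.any(np.abs(dt - interval) > 0.01 * interval):
                raise LoadError(
                    f"{path}: non-uniform frame spacing for track {track_id!r}"
                )
        else:
            interval = 3.0
        onset_flags = grp["anaphase_onset_flag"].to_numpy()
        onset_pos = int(np.argmax(onset_flags)) if onset_flags.any() else 0
        frames = [
            ((r.p1x, r.p1z), (r.p2x, r.p2z)) for r in grp.itertuples(index=False)
        ]
        tracks.append(
            SpindleTrack(
                frames=frames,
                frame_interval=interval,
                anaphase_onset_frame=onset_pos,
                track_id=str(track_id),
            )
        )
    return tracks


def write_spindles(tracks: Iterable[SpindleTrack], path) -> None:
    rows = []
    for tr in tracks:
        for i, (p1, p2) in enumerate(tr.frames):
            rows.append(
                (
                    tr.track_id,
                    i,
                    i * tr.frame_interval,
                    p1[0],
                    p1[1],
                    p2[0],
                    p2[1],
                    int(i == tr.anaphase_onset_frame),
                )
            )
    pd.DataFrame(rows, columns=SPINDLE_COLUMNS).to_csv(path, index=False)


def write_masks(masks: Sequence[BinaryMask], path) -> None:
    """Write masks as a multi-page TIFF plus a JSON sidecar carrying the
    physical pixel size and per-page origins."""
    path = Path(path)
    stack = np.stack([m.grid.astype(np.uint8) for m in masks])
    tifffile.imwrite(path, stack)
    sidecar = {
        "pixel_size_um": [m.pixel_size for m in masks],
        "origin_um": [list(m.origin) for m in masks],
        "y_convention": "math",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_masks(path) -> list[BinaryMask]:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise LoadError(f"{path}: missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("y_convention") not in ("math", "image"):
        raise LoadError(f"{path}: sidecar must declare a known y_convention")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    flip = sidecar["y_convention"] == "image"
    masks = []
    for page, ps, origin in zip(stack, sidecar["pixel_size_um"], sidecar["origin_um"]):
        grid = page.astype(bool)
        if flip:
            grid = grid[::-1]
        masks.append(BinaryMask(grid=grid, pixel_size=float(ps), origin=tuple(origin)))
    return masks


def tidy_measurements(records: Iterable[tuple[str, float, str, float]]) -> pd.DataFrame:
    """Tidy result table: one measurement per row
    (cell_id, frame_time, metric, value)."""
    return pd.DataFrame(records, columns=["cell_id", "frame_time", "metric", "value"])
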