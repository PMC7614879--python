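"""Figure-level analyses chaining the measurement modules over cohorts.

These functions take collections of division events / spindle tracks —
loaded from files or produced by :mod:`mitoshape.synthetic` — and emit tidy
per-cell metric tables plus deterministic JSON summaries.  Cohorts are
partitioned into pseudo-experiments (round-robin on event order) so the
across-experiment mean ± SD convention of the summaries is exercised even
on simulated data.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .orientation import SpindleTrack, angle_series
from .respreading import DivisionEvent, exit_metrics
from .stats import rank_sum_test, summarize_cohort
from .synthetic import Cohort, generate_cohort

__all__ = [
    "measure_events",
    "measure_spindles",
    "cohort_report",
    "run_preset_pipeline",
    "dump_json",
]

N_PSEUDO_EXPERIMENTS = 3


def measure_events(
    events: Iterable[DivisionEvent],
    condition: str = "",
    n_experiments: int = N_PSEUDO_EXPERIMENTS,
    similarity_offset_min: float = 25.0,
    asymmetry_threshold: float = 2.0,
    pixel_size: float | None = None,
    include_similarity: bool = True,
) -> pd.DataFrame:
    """Per-event exit metrics as one tidy row per division."""
    rows = []
    for i, ev in enumerate(events):
        m = exit_metrics(
            ev,
            similarity_offset_min=similarity_offset_min,
            asymmetry_threshold=asymmetry_threshold,
            pixel_size=pixel_size,
            include_similarity=include_similarity,
            require_neb=False,
        )
        sim = (
            m.mother_similarity_series[0][1] if m.mother_similarity_series else None
        )
        rows.append(
            {
                "event_id": ev.event_id or str(i),
                "condition": condition,
                "experiment": i % n_experiments,
                "metaphase_area_um2": m.metaphase_area,
                "respread_ratio": m.respread_ratio,
                "daughter_area_ratio": m.daughter_area_ratio,
                "asymmetric": m.asymmetric,
                "metaphase_feret_um": m.metaphase_feret,
                "mother_similarity": sim,
            }
        )
    return pd.DataFrame(rows)


def measure_spindles(
    tracks: Iterable[SpindleTrack],
    condition: str = "",
    tilt_threshold: float = 30.0,
    n_experiments: int = N_PSEUDO_EXPERIMENTS,
) -> pd.DataFrame:
    """Per-track spindle angle summary (angle at +21 min, cumulative change,
    misorientation flag)."""
    rows = []
    for i, tr in enumerate(tracks):
        m = angle_series(tr, tilt_threshold=tilt_threshold)
        rows.append(
            {
                "track_id": tr.track_id or str(i),
                "condition": condition,
                "experiment": i % n_experiments,
                "angle_at_21_deg": m.angle_at_21,
                "cumulative_change_deg": m.cumulative_change,
                "misoriented": m.misoriented,
            }
        )
    return pd.DataFrame(rows)


def cohort_report(
    event_metrics: pd.DataFrame,
    spindle_metrics: pd.DataFrame | None = None,
) -> dict:
    """Deterministic summary of a metrics table: per-condition summaries
    (across-experiment mean ± SD) plus pairwise rank-sum tests on the
    per-cell distributions when two or more conditions are present."""
    report: dict = {"tool": "mitoshape", "version": __version__}
    summaries = summarize_cohort(
        event_metrics,
        metric_cols=[
            "respread_ratio",
            "daughter_area_ratio",
            "mother_similarity",
            "metaphase_feret_um",
        ],
        misoriented_col=None,
    )
    report["conditions"] = [s.to_dict() for s in summaries]
    if spindle_metrics is not None and len(spindle_metrics):
        spin = summarize_cohort(
            spindle_metrics,
            metric_cols=["angle_at_21_deg", "cumulative_change_deg"],
            asymmetric_col=None,
        )
        report["spindle_conditions"] = [s.to_dict() for s in spin]
    conditions = sorted(event_metrics["condition"].unique())
    tests = {}
    for i, ca in enumerate(conditions):
        for cb in conditions[i + 1 :]:
            for metric in ("respread_ratio", "daughter_area_ratio"):
                a = event_metrics.loc[
                    event_metrics["condition"] == ca, metric
                ].dropna()
                b = event_metrics.loc[
                    event_metrics["condition"] == cb, metric
                ].dropna()
                if len(a) and len(b):
                    r = rank_sum_test(a, b)
                    tests[f"{metric}:{ca}_vs_{cb}"] = {
                        "u": r.u,
                        "p": r.p,
                        "method": r.method,
                        "n_a": r.n_a,
                        "n_b": r.n_b,
                    }
    if tests:
        report["rank_sum_tests"] = tests
    return report


def dump_json(obj: dict, path=None) -> str:
    """Canonical JSON serialization (sorted keys, fixed separators) so that
    identical inputs give byte-identical files."""
    text = json.dumps(_roundtrip_floats(obj), sort_keys=True, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _roundtrip_floats(obj):
    if isinstance(obj, dict):
        return {k: _roundtrip_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtrip_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_preset_pipeline(
    preset: str,
    n: int = 30,
    seed: int = 0,
    outdir=None,
    pixel_size: float | None = None,
) -> dict:
    """simulate → respread → spindle → report for one preset.

    Returns the summary report; when ``outdir`` is given, also writes the
    manifest, the per-cell metric tables, the summary JSON and a run log.
    """
    cohort = generate_cohort(preset, n=n, seed=seed)
    events_df = measure_events(cohort.events, condition=preset, pixel_size=pixel_size)
    spindle_df = measure_spindles(cohort.spindle_tracks, condition=preset)
    report = cohort_report(events_df, spindle_df)
    report["preset"] = preset
    report["n"] = n
    report["seed"] = seed
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_text = dump_json(cohort.manifest, outdir / "manifest.json")
        events_df.to_csv(outdir / "event_metrics.csv", index=False)
        spindle_df.to_csv(outdir / "spindle_metrics.csv", index=False)
        dump_json(report, outdir / "summary.json")
        config_hash = hashlib.sha256(manifest_text.encode()).hexdigest()[:16]
        n_excluded = int(events_df["daughter_area_ratio"].isna().sum())
        (outdir / "run.log").write_text(
            "\n".join(
                [
                    f"tool: mitoshape {__version__}",
                    f"preset: {preset}",
                    f"seed: {seed}",
                    f"n_events: {n}",
                    f"manifest_sha256: {config_hash}",
                    f"excluded_events: {n_excluded}",
                ]
            )
            + "\n"
        )
    return report
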