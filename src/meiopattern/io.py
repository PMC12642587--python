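"""Table and trace file I/O, pipeline configuration and the orchestrator.

Schemas (all plain text):

* detection tables — CSV with columns ``frame, nucleus_id, channel, x, y,
  z`` (µm), ``amplitude, foreground, effect_size``; extra columns survive
  a round trip.
* centroid tables — CSV with ``frame, nucleus_id, x, y, z, volume,
  sphericity``.
* trace files — JSON list of ``{trace_id, nucleus_id, is_X, points}`` with
  ``points`` an ordered list of [x, y, z] in µm.
* localization tables — CSV with ``x, y, z`` (nm), ``precision_xy,
  precision_z, channel`` (SMAP-style columns configurable via rename).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PipelineConfig",
    "read_table",
    "write_table",
    "read_traces",
    "write_traces",
    "run_pipeline",
]

DETECTION_COLUMNS = ["frame", "nucleus_id", "channel", "x", "y", "z",
                     "amplitude", "foreground", "effect_size"]
CENTROID_COLUMNS = ["frame", "nucleus_id", "x", "y", "z", "volume", "sphericity"]
LOCALIZATION_COLUMNS = ["x", "y", "z", "precision_xy", "precision_z", "channel"]


@dataclass
class PipelineConfig:
    """Defaults follow the published acquisition and filter settings."""

    seed: int = 0
    n_frames: int = 40
    frame_interval_min: float = 1.0
    transit_h_per_row: float = 1.1
    trace_spacing_um: float = 0.12
    effect_size_thresholds: dict = field(
        default_factory=lambda: {"halo_cosa1": 1.1, "msh5_halo": 2.1, "cosa1_mng": 3.0}
    )
    dbscan_eps_nm: float = 100.0
    dbscan_min_pts: int = 20
    centerline_gate_nm: float = 350.0
    centerline_keep_nm: float = 120.0
    z_range_nm: tuple = (-300.0, 300.0)
    max_precision_xy_nm: float = 15.0
    max_precision_z_nm: float = 25.0
    nucleus_diameter_um: tuple = (3.5, 8.0)
    min_sphericity: float = 0.75
    arm_boundary: float = 0.33
    version: str = "0.1.0"


def read_table(path, kind: str | None = None, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking the schema for known kinds.

    ``kind`` is one of ``detections``, ``centroids``, ``localizations``;
    missing required columns raise a ``ValueError`` naming them.
    """
    df = pd.read_csv(path)
    req = required or {
        "detections": DETECTION_COLUMNS,
        "centroids": CENTROID_COLUMNS,
        "localizations": LOCALIZATION_COLUMNS,
        None: [],
    }[kind]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} is missing column(s): {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_traces(traces, path) -> None:
    """Write polyline traces as JSON (points in µm)."""
    recs = []
    for t in traces:
        recs.append({
            "trace_id": int(t["trace_id"]),
            "nucleus_id": int(t["nucleus_id"]),
            "is_X": bool(t.get("is_X", False)),
            "points": np.asarray(t["points"], float).tolist(),
        })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(recs, fh)


def read_traces(path) -> list[dict]:
    with open(path) as fh:
        recs = json.load(fh)
    for r in recs:
        r["points"] = np.asarray(r["points"], float)
    return recs


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Simulate → stage → trace → classify → patterning statistics.

    Runs the full live-imaging branch on generated data, writes the staged
    nucleus table, the focus-group table and the arm-bias/interference
    statistics under ``out_dir`` together with a manifest of every
    parameter, and returns the manifest.  Everything downstream of the
    seed is deterministic, so two runs with the same config are
    byte-identical.
    """
    from . import germline_staging, patterning_stats, synthetic_data, trace_mapping

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    cfg = synthetic_data.GermlineConfig(seed=config.seed,
                                        transit_h_per_row=config.transit_h_per_row,
                                        frame_interval_min=config.frame_interval_min)
    kin = synthetic_data.FocusKineticsConfig(seed=config.seed)
    tracks, detections, truth = synthetic_data.gen_germline_movie(
        cfg, kin, n_frames=config.n_frames, rng=rng
    )
    staged, model = germline_staging.stage_nuclei(
        tracks, detections, transit_h_per_row=config.transit_h_per_row
    )
    write_table(staged, out / "staged_nuclei.csv")

    traces_raw, placements = synthetic_data.gen_sc_traces(kin, n_nuclei=4, rng=rng)
    det = synthetic_data.gen_trace_movie_detections(
        traces_raw, placements, kin, n_frames=config.n_frames, rng=rng
    )
    traces = [
        trace_mapping.resample_trace(t["points"], config.trace_spacing_um,
                                     trace_id=t["trace_id"], nucleus_id=t["nucleus_id"],
                                     is_X=t["is_X"])
        for t in traces_raw
    ]
    group_rows = []
    for tr in traces:
        assigned = []
        for r in det.itertuples(index=False):
            tid, arc, dist = trace_mapping.assign_focus((r.x, r.y, r.z), traces)
            if tid == tr.trace_id:
                assigned.append((r.frame, arc, r.amplitude))
        adf = pd.DataFrame(assigned, columns=["frame", "arc_um", "intensity"])
        for g in trace_mapping.group_and_classify(adf, tr, config.n_frames):
            group_rows.append((g.trace_id, g.label, g.lo, g.hi, g.mean_position_um,
                               len(g.frames_detected)))
    groups = pd.DataFrame(group_rows, columns=["trace_id", "label", "lo_um", "hi_um",
                                               "mean_position_um", "n_frames_detected"])
    write_table(groups, out / "focus_groups.csv")

    # spread presets emit already-folded values
    folded = patterning_stats.FoldedPositions(
        synthetic_data.gen_spread_foci("arm_biased_late_CO", 200, rng=rng), label="late_CO"
    )
    uniform = patterning_stats.FoldedPositions(
        synthetic_data.gen_spread_foci("uniform", 200, rng=rng), label="early_MSH5"
    )
    comparison = patterning_stats.compare_distributions([folded, uniform])
    write_table(comparison, out / "distribution_comparison.csv")

    manifest = {"config": asdict(config), "n_nuclei": int(tracks["nucleus_id"].nunique()),
                "n_groups": int(len(groups)),
                "onset_position_um": float(model.onset_position)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
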