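"""Mapping foci onto synaptonemal-complex traces and classifying their dynamics.

Traced SCs (3D polylines) are spline-smoothed and resampled at equidistant
arc-length points (120 nm default).  Foci are assigned to the nearest
trace, given an arc-length coordinate, and surrounded by an
orientation-dependent interval whose half-width interpolates between the
lateral and axial resolution limits.  Intervals overlapping across frames
are merged into focus groups and labelled *persistent* (detected in nearly
every analyzed frame) or *blinking* (repeatedly absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep

__all__ = [
    "SCTrace",
    "FocusGroup",
    "resample_trace",
    "estimate_channel_offset",
    "assign_focus",
    "interval_half_width",
    "build_intervals",
    "group_and_classify",
    "flag_untrackable",
]

DEFAULT_SPACING_UM = 0.12          # 120 nm
DEFAULT_R_XY_UM = 0.25             # lateral resolution limit
DEFAULT_R_Z_UM = 0.60              # axial resolution limit
DEFAULT_REJECT_DISTANCE_UM = 0.75
PERSISTENCE_FRACTION = 0.95
MIN_BLINK_DETECTIONS = 2


@dataclass
class SCTrace:
    trace_id: int
    nucleus_id: int
    points: np.ndarray              # resampled, equidistant arc-length samples
    spacing_um: float
    is_X: bool = False
    trackable: bool = True

    @property
    def length_um(self) -> float:
        return (len(self.points) - 1) * self.spacing_um

    def arc_positions(self) -> np.ndarray:
        return np.arange(len(self.points)) * self.spacing_um

    def tangents(self) -> np.ndarray:
        """Unit tangent at each resampled point (central differences)."""
        t = np.gradient(self.points, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def tangent_elevation(self) -> np.ndarray:
        """Angle (rad) between the local tangent and the lateral (xy) plane."""
        t = self.tangents()
        return np.arcsin(np.clip(np.abs(t[:, 2]), 0.0, 1.0))


@dataclass
class FocusGroup:
    trace_id: int
    lo: float
    hi: float
    frames_detected: set = field(default_factory=set)
    n_frames_analyzed: int = 0
    label: str = ""
    mean_position_um: float = np.nan
    intensities: np.ndarray | None = None   # per analyzed frame, 0 when absent


def resample_trace(
    raw_points: np.ndarray,
    spacing_um: float = DEFAULT_SPACING_UM,
    trace_id: int = 0,
    nucleus_id: int = 0,
    is_X: bool = False,
    smooth: float | None = None,
) -> SCTrace:
    """Spline-smooth a raw polyline and sample it at equidistant arc length.

    The reported trace length is ``(n_samples - 1) * spacing``; resampling
    an already-resampled trace reproduces it to well under a nanometre.
    """
    pts = np.asarray(raw_points, float)
    if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 3:
        raise ValueError("need an (N>=4, 3) polyline")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("degenerate polyline: repeated points")
    if smooth is None:
        smooth = 0.0
    tck, _ = splprep(pts.T, s=smooth, k=3)
    # dense evaluation, then arc-length-uniform resampling (interparc-style)
    u = np.linspace(0, 1, max(20 * len(pts), 1000))
    dense = np.asarray(splev(u, tck)).T
    dseg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(dseg)])
    total = arc[-1]
    n = int(np.floor(total / spacing_um)) + 1
    targets = np.arange(n) * spacing_um
    out = np.column_stack([np.interp(targets, arc, dense[:, i]) for i in range(3)])
    return SCTrace(trace_id, nucleus_id, out, spacing_um, is_X=is_X)


def estimate_channel_offset(stack_a: np.ndarray, stack_b: np.ndarray) -> tuple[int, int, int]:
    """Integer 3D offset of channel B relative to channel A.

    Per-frame, per-axis shifts are estimated from the cross-correlation of
    maximum-intensity projections; the final offset is the mode of the
    per-frame estimates and is meant to be applied uniformly to all
    frames.  Input stacks are (T, Z, Y, X).
    """
    a = np.asarray(stack_a, float)
    b = np.asarray(stack_b, float)
    if a.shape != b.shape or a.ndim != 4:
        raise ValueError("need two equal-shape (T, Z, Y, X) stacks")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("no structure: flat image")
    shifts = np.zeros((a.shape[0], 3), int)
    for t in range(a.shape[0]):
        for axis in range(3):  # z, y, x
            proj_axes = tuple(ax for ax in (1, 2, 3) if ax != axis + 1)
            pa = a[t].max(axis=tuple(i - 1 for i in proj_axes)).ravel()
            pb = b[t].max(axis=tuple(i - 1 for i in proj_axes)).ravel()
            pa = pa - pa.mean()
            pb = pb - pb.mean()
            corr = np.correlate(pb, pa, mode="full")
            shifts[t, axis] = int(np.argmax(corr)) - (len(pa) - 1)
    out = []
    for axis in range(3):
        vals, counts = np.unique(shifts[:, axis], return_counts=True)
        out.append(int(vals[np.argmax(counts)]))
    return tuple(out)


def assign_focus(
    position: np.ndarray,
    traces: Sequence[SCTrace],
    reject_distance_um: float = DEFAULT_REJECT_DISTANCE_UM,
) -> tuple[int | None, float, float]:
    """Nearest-trace assignment; returns (trace_id, arc_position_um, distance).

    The focus is snapped to the nearest resampled point over all traces;
    ties between traces break toward the lower trace_id.  A focus farther
    than ``reject_distance_um`` from every trace is unassigned
    (``(None, nan, distance)``).
    """
    p = np.asarray(position, float)
    best = (np.inf, None, np.nan)
    for tr in sorted(traces, key=lambda t: t.trace_id):
        d = np.linalg.norm(tr.points - p, axis=1)
        i = int(np.argmin(d))
        # strictly-less keeps the lowest trace_id on exact ties
        if d[i] < best[0] - 1e-12:
            best = (float(d[i]), tr.trace_id, i * tr.spacing_um)
    dist, tid, arc = best
    if tid is None or dist > reject_distance_um:
        return None, np.nan, dist
    return tid, arc, dist


def interval_half_width(
    elevation_rad: float,
    r_xy_um: float = DEFAULT_R_XY_UM,
    r_z_um: float = DEFAULT_R_Z_UM,
) -> float:
    """Resolution-limited half-width at a given tangent elevation φ.

    w = sqrt((r_xy·cosφ)² + (r_z·sinφ)²): the in-plane limit for a trace
    lying in the imaging plane, the axial limit for a trace along z.
    """
    c, s = np.cos(elevation_rad), np.sin(elevation_rad)
    return float(np.hypot(r_xy_um * c, r_z_um * s))


def build_intervals(
    arc_um: float,
    trace: SCTrace,
    r_xy_um: float = DEFAULT_R_XY_UM,
    r_z_um: float = DEFAULT_R_Z_UM,
) -> tuple[float, float]:
    """Uncertainty interval around an assigned arc position, clipped to the trace."""
    i = int(round(arc_um / trace.spacing_um))
    i = min(max(i, 0), len(trace.points) - 1)
    phi = trace.tangent_elevation()[i]
    w = interval_half_width(phi, r_xy_um, r_z_um)
    return (max(arc_um - w, 0.0), min(arc_um + w, trace.length_um))


def group_and_classify(
    assignments: pd.DataFrame,
    trace: SCTrace,
    n_frames: int,
    persistence_fraction: float = PERSISTENCE_FRACTION,
    min_blink_detections: int = MIN_BLINK_DETECTIONS,
    r_xy_um: float = DEFAULT_R_XY_UM,
    r_z_um: float = DEFAULT_R_Z_UM,
) -> list[FocusGroup]:
    """Merge per-frame intervals on one trace into labelled focus groups.

    ``assignments`` needs columns ``frame, arc_um`` and optionally
    ``intensity``.  Intervals that transitively overlap across frames form
    one group; a group detected in at least ``persistence_fraction`` of the
    analyzed frames is *persistent*, otherwise *blinking* (requiring at
    least ``min_blink_detections`` detections to count at all).  The
    per-frame intensity series carries zeros for undetected frames.
    """
    if assignments.empty:
        return []
    recs = []
    for r in assignments.itertuples(index=False):
        lo, hi = build_intervals(r.arc_um, trace, r_xy_um, r_z_um)
        inten = getattr(r, "intensity", 1.0)
        recs.append((lo, hi, int(r.frame), float(r.arc_um), float(inten)))
    recs.sort()
    groups: list[list[tuple]] = []
    cur = [recs[0]]
    cur_hi = recs[0][1]
    for rec in recs[1:]:
        if rec[0] <= cur_hi:            # transitive overlap
            cur.append(rec)
            cur_hi = max(cur_hi, rec[1])
        else:
            groups.append(cur)
            cur = [rec]
            cur_hi = rec[1]
    groups.append(cur)

    out = []
    for members in groups:
        frames = {m[2] for m in members}
        if len(frames) < min_blink_detections:
            continue
        label = (
            "persistent"
            if len(frames) >= persistence_fraction * n_frames
            else "blinking"
        )
        inten = np.zeros(n_frames)
        for m in members:
            if m[2] < n_frames:
                inten[m[2]] = m[4]
        out.append(FocusGroup(
            trace_id=trace.trace_id,
            lo=min(m[0] for m in members),
            hi=max(m[1] for m in members),
            frames_detected=frames,
            n_frames_analyzed=n_frames,
            label=label,
            mean_position_um=float(np.mean([m[3] for m in members])),
            intensities=inten,
        ))
    return out


def flag_untrackable(
    trace: SCTrace,
    max_elevation_deg: float = 60.0,
    max_fraction: float = 0.2,
) -> bool:
    """True iff the trace can be tracked reliably.

    A trace is untrackable when more than ``max_fraction`` of its arc
    length runs steeper than ``max_elevation_deg`` against the imaging
    plane (where axial resolution makes focus assignment unreliable), or
    when it is the X chromosome, which is always excluded.
    """
    if trace.is_X:
        return False
    phi = trace.tangent_elevation()
    frac = float(np.mean(phi > np.deg2rad(max_elevation_deg)))
    return frac <= max_fraction
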