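"""Meiotic pseudotime staging of germline nuclei.

The *C. elegans* gonad is an assembly line: nuclei move row by row toward
the late-pachytene transition, so a nucleus's position along the gonad is a
proxy for meiotic time.  This module linearizes the gonad (PCA rotation +
LOWESS centerline), locates late-pachytene onset as the inflection point of
a cumulative-Gaussian fit to the nucleus-level log focus intensity, and
converts positions to rows and hours via the measured row spacing and
per-row transit time (1.1 h/row by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.stats import norm, spearmanr
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "StagingModel",
    "rotate_to_axis",
    "fit_centerline",
    "assign_linear_position",
    "row_spacing",
    "fit_onset",
    "rows_to_time",
    "estimate_speed",
    "stage_nuclei",
]

DEFAULT_TRANSIT_H_PER_ROW = 1.1


@dataclass
class StagingModel:
    rotation: np.ndarray            # 3x3 rigid rotation
    centerline: "Centerline"
    direction: int                  # +1 if progression increases x, else -1
    onset_position: float           # µm along the centerline
    row_spacing_um: float
    transit_h_per_row: float = DEFAULT_TRANSIT_H_PER_ROW


def rotate_to_axis(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly rotate centroids so the first coordinate carries maximal variance.

    Returns ``(rotated, R)`` with ``rotated = (centroids - mean) @ R.T``.
    The rotation is proper (det = +1), so all pairwise distances are
    preserved exactly.
    """
    pts = np.asarray(centroids, float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 centroids")
    centered = pts - pts.mean(axis=0)
    # principal axes by SVD; enforce a proper rotation
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300) and pts.shape[1] > 1:
        # collinear input still rotates fine, but warn via variance check later
        pass
    r = vt
    if np.linalg.det(r) < 0:
        r = r.copy()
        r[-1] *= -1
    return centered @ r.T, r


class Centerline:
    """Smooth map from the progression coordinate to transverse coordinates."""

    def __init__(self, x: np.ndarray, transverse: np.ndarray, frac: float = 0.3):
        x = np.asarray(x, float)
        transverse = np.atleast_2d(np.asarray(transverse, float))
        if transverse.shape[0] == x.size:
            transverse = transverse.T
        if not (np.isfinite(x).all() and np.isfinite(transverse).all()):
            raise ValueError("non-finite coordinates")
        order = np.argsort(x)
        self._x = x[order]
        self._curves = []
        for row in transverse:
            sm = lowess(row[order], self._x, frac=frac, return_sorted=True)
            self._curves.append(sm)
        self.domain = (float(self._x[0]), float(self._x[-1]))
        # dense arc-length table for foot-point projection
        xs = np.linspace(*self.domain, 2048)
        ys = self(xs)
        pts = np.column_stack([xs, ys])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._arc_x = xs
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])
        self._pts = pts

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        out = [np.interp(x, c[:, 0], c[:, 1]) for c in self._curves]
        return np.stack(out, axis=-1)

    def arc_length_at(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, float), self._arc_x, self._arc)


def fit_centerline(rotated: np.ndarray, frac: float = 0.3) -> Centerline:
    """LOWESS centerline through rotated centroids.

    The first column is the progression coordinate; the remaining columns
    are smoothed against it.
    """
    pts = np.asarray(rotated, float)
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 centroids to fit a centerline")
    return Centerline(pts[:, 0], pts[:, 1:].T, frac=frac)


def assign_linear_position(
    centroids: np.ndarray, centerline: Centerline
) -> tuple[np.ndarray, np.ndarray]:
    """Arc length along the centerline at the foot point of each centroid.

    Returns ``(positions_um, clamped)``; centroids whose foot point falls
    at the domain boundary are flagged as clamped.
    """
    pts = np.atleast_2d(np.asarray(centroids, float))
    tree = cKDTree(centerline._pts)
    _, idx = tree.query(pts[:, : centerline._pts.shape[1]])
    pos = centerline._arc[idx]
    clamped = (idx == 0) | (idx == len(centerline._arc) - 1)
    # flag points lying outside the fitted x-domain
    x = pts[:, 0]
    clamped |= (x < centerline.domain[0]) | (x > centerline.domain[1])
    return pos, clamped


def row_spacing(centroids: np.ndarray) -> float:
    """Median nearest-neighbor distance between nucleus centroids (µm)."""
    pts = np.asarray(centroids, float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(np.median(d[:, 1]))


def _cum_gauss(x, low, high, x0, w):
    return low + (high - low) * norm.cdf((x - x0) / w)


def fit_onset(
    positions: np.ndarray,
    log_amplitudes: np.ndarray,
    n_starts: int = 5,
) -> tuple[int, float, dict]:
    """Locate late-pachytene onset from the nucleus-level intensity profile.

    Least-squares fit of ``low + (high-low)*Φ((x-x0)/w)`` to the log median
    focus amplitude versus gonad position, multi-started over ``n_starts``
    initial midpoints with the width constrained positive.  Returns
    ``(direction, onset_position, fit_info)``; ``direction`` is +1 when
    intensity (hence meiotic progression) increases with position.

    Raises ``RuntimeError`` when no start converges and ``ValueError`` for
    a profile with no detectable transition.
    """
    x = np.asarray(positions, float)
    y = np.asarray(log_amplitudes, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 20:
        raise ValueError("need amplitudes for at least 20 nuclei")
    span = x.max() - x.min()
    if span <= 0 or np.ptp(y) < 1e-12:
        raise ValueError("no transition: flat intensity profile")

    best = None
    mids = np.quantile(x, np.linspace(0.15, 0.85, n_starts))
    for mid in mids:
        p0 = [np.quantile(y, 0.1), np.quantile(y, 0.9), mid, span / 10.0]
        try:
            popt, _ = curve_fit(
                _cum_gauss, x, y, p0=p0,
                bounds=([-np.inf, -np.inf, x.min() - span, 1e-6],
                        [np.inf, np.inf, x.max() + span, span]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((y - _cum_gauss(x, *popt)) ** 2))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        raise RuntimeError("cumulative-Gaussian onset fit did not converge")
    resid, (low, high, x0, w) = best
    flat = float(np.sum((y - y.mean()) ** 2))
    if flat > 0 and resid > 0.99 * flat:
        raise ValueError("no transition: fit does not improve on a flat profile")
    direction = 1 if high >= low else -1
    if not (x.min() <= x0 <= x.max()):
        raise ValueError("no transition: onset outside the observed range")
    return direction, float(x0), {
        "low": min(low, high), "high": max(low, high), "width": float(w),
        "residual": resid,
    }


def rows_to_time(rows: float, transit_h_per_row: float = DEFAULT_TRANSIT_H_PER_ROW) -> float:
    """Convert a signed row count to hours; 5 rows at 1.1 h/row is 5.5 h."""
    if transit_h_per_row <= 0:
        raise ValueError("transit must be positive")
    return rows * transit_h_per_row


def estimate_speed(
    staged: pd.DataFrame,
    row_spacing_um: float,
    frame_interval_min: float = 1.0,
) -> tuple[float, float, pd.DataFrame]:
    """Per-row transit time from per-nucleus position-vs-time slopes.

    ``staged`` needs columns ``nucleus_id, frame, position_um``.  For each
    nucleus a linear model position ~ time gives a speed in µm/h; transit
    (h/row) = row_spacing / speed.  Returns ``(mean, sd, per_nucleus)``
    across nuclei; stationary nuclei are flagged ``no_movement`` and
    excluded from the aggregate.
    """
    recs = []
    for nid, grp in staged.groupby("nucleus_id"):
        if len(grp) < 2:
            continue  # single-frame track: skip
        t_h = grp["frame"].to_numpy(float) * frame_interval_min / 60.0
        p = grp["position_um"].to_numpy(float)
        slope = np.polyfit(t_h, p, 1)[0]  # µm / h
        if abs(slope) < 1e-9:
            recs.append((nid, slope, np.nan, True))
        else:
            recs.append((nid, slope, row_spacing_um / abs(slope), False))
    per_nucleus = pd.DataFrame(
        recs, columns=["nucleus_id", "speed_um_per_h", "transit_h_per_row", "no_movement"]
    )
    ok = per_nucleus.loc[~per_nucleus["no_movement"], "transit_h_per_row"]
    if ok.empty:
        return np.inf, np.nan, per_nucleus
    return float(ok.mean()), float(ok.std(ddof=1)) if len(ok) > 1 else 0.0, per_nucleus


def stage_nuclei(
    centroid_table: pd.DataFrame,
    focus_table: pd.DataFrame,
    transit_h_per_row: float = DEFAULT_TRANSIT_H_PER_ROW,
    frac: float = 0.3,
    frame: int | None = 0,
) -> tuple[pd.DataFrame, StagingModel]:
    """Full staging pipeline on one (frame of a) centroid + focus table.

    Fits rotation, centerline and onset, then returns a staged-nucleus
    table with ``position_um`` (signed distance to onset, negative before
    onset), ``position_rows`` and ``time_to_onset_h``.
    """
    ct = centroid_table
    if frame is not None and "frame" in ct.columns:
        ct = ct[ct["frame"] == frame]
    cent = ct[["x", "y", "z"]].to_numpy(float)
    rotated, rot = rotate_to_axis(cent)
    cl = fit_centerline(rotated, frac=frac)
    pos, _ = assign_linear_position(rotated, cl)
    spacing = row_spacing(cent)

    amp = (
        focus_table.groupby("nucleus_id")["amplitude"].median()
        .pipe(lambda s: np.log(s / s.median()))
    )
    nid = ct["nucleus_id"].to_numpy()
    amp_per_nucleus = amp.reindex(nid).to_numpy(float)
    direction, onset, _info = fit_onset(pos, amp_per_nucleus)

    signed = (pos - onset) * direction
    staged = pd.DataFrame({
        "nucleus_id": nid,
        "position_um": signed,
        "position_rows": signed / spacing,
        "time_to_onset_h": rows_to_time(signed / spacing, transit_h_per_row),
    })
    model = StagingModel(rot, cl, direction, onset, spacing, transit_h_per_row)
    return staged, model
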