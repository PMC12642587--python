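"""Focus detection, filtering and intensity dynamics.

Covers the quality gates applied to segmented nuclei (sphere-equivalent
diameter 3.5–8 µm, sphericity ≥ 0.75), a Laplacian-of-Gaussian spot
detector with 3D Gaussian refinement and Hedges'-g effect-size scoring,
the per-channel effect-size filter (defaults 1.1 / 2.1 / 3.0), photobleach
correction by per-frame histogram matching, the bleach-safe frame cutoff,
and per-nucleus count/colocalization statistics.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_nuclei",
    "detect_foci",
    "hedges_g",
    "effect_size_filter",
    "bleach_correct",
    "bleach_safe_cutoff",
    "count_stats",
    "link_tracks",
    "DEFAULT_EFFECT_SIZE_THRESHOLDS",
]

DEFAULT_EFFECT_SIZE_THRESHOLDS: Mapping[str, float] = {
    "halo_cosa1": 1.1,
    "msh5_halo": 2.1,
    "cosa1_mng": 3.0,
}

DIAMETER_RANGE_UM = (3.5, 8.0)
MIN_SPHERICITY = 0.75


def sphere_equivalent_diameter(volume_um3: np.ndarray) -> np.ndarray:
    return np.cbrt(6.0 * np.asarray(volume_um3, float) / np.pi)


def filter_nuclei(segments: pd.DataFrame) -> pd.DataFrame:
    """Keep nuclei with diameter in [3.5, 8] µm and sphericity ≥ 0.75.

    Rows lacking a sphericity value are dropped with a warning.  Both
    bounds are inclusive.
    """
    seg = segments.copy()
    missing = seg["sphericity"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} nuclei without sphericity")
        seg = seg[~missing]
    d = sphere_equivalent_diameter(seg["volume"].to_numpy(float))
    keep = (
        (d >= DIAMETER_RANGE_UM[0])
        & (d <= DIAMETER_RANGE_UM[1])
        & (seg["sphericity"].to_numpy(float) >= MIN_SPHERICITY)
    )
    return seg[keep]


# ---------------------------------------------------------------------------
# spot detection
# ---------------------------------------------------------------------------


def hedges_g(sample: np.ndarray, background: np.ndarray) -> float:
    """Small-sample-corrected standardized mean difference."""
    a = np.asarray(sample, float).ravel()
    b = np.asarray(background, float).ravel()
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        return np.nan
    s_pooled = np.sqrt(
        ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        return np.inf if a.mean() > b.mean() else 0.0
    g = (a.mean() - b.mean()) / s_pooled
    correction = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(g * correction)


def _gauss3d(coords, amp, z0, y0, x0, sz, syx, offset):
    z, y, x = coords
    return offset + amp * np.exp(
        -((z - z0) ** 2) / (2 * sz**2)
        - ((y - y0) ** 2 + (x - x0) ** 2) / (2 * syx**2)
    )


def detect_foci(
    stack: np.ndarray,
    voxel_size_um: tuple[float, float, float] = (0.3, 0.1, 0.1),
    sigma_um: float = 0.15,
    threshold_rel: float = 0.1,
    patch_radius: tuple[int, int, int] = (3, 5, 5),
) -> pd.DataFrame:
    """LoG candidate detection refined by a 3D Gaussian fit.

    Returns a table with z/y/x in µm, fitted ``amplitude``, ``foreground``
    (integral of the fitted Gaussian) and ``effect_size`` (Hedges' g of
    focus voxels within 1σ of the fit center versus a 1.5–3σ background
    shell).  Empty or blank stacks yield an empty table.
    """
    from skimage.feature import blob_log

    img = np.asarray(stack, float)
    if img.size == 0 or np.ptp(img) == 0:
        return pd.DataFrame(
            columns=["z", "y", "x", "amplitude", "foreground", "effect_size"]
        )
    vz, vy, vx = voxel_size_um
    sigmas = (sigma_um / vz, sigma_um / vy, sigma_um / vx)
    blobs = blob_log(
        img, min_sigma=[s * 0.7 for s in sigmas], max_sigma=[s * 1.6 for s in sigmas],
        num_sigma=3, threshold=threshold_rel * np.ptp(img),
    )
    rows = []
    rz, ry, rx = patch_radius
    for zc, yc, xc, *_ in blobs:
        zc, yc, xc = int(round(zc)), int(round(yc)), int(round(xc))
        sl = (
            slice(max(zc - rz, 0), zc + rz + 1),
            slice(max(yc - ry, 0), yc + ry + 1),
            slice(max(xc - rx, 0), xc + rx + 1),
        )
        patch = img[sl]
        zz, yy, xx = np.mgrid[sl]
        p0 = [patch.max() - patch.min(), zc, yc, xc, sigmas[0], sigmas[1], patch.min()]
        try:
            popt, _ = curve_fit(
                _gauss3d, (zz.ravel(), yy.ravel(), xx.ravel()), patch.ravel(),
                p0=p0, maxfev=5000,
            )
        except RuntimeError:
            continue
        amp, z0, y0, x0, sz, syx, offset = popt
        sz, syx = abs(sz), abs(syx)
        foreground = amp * (2 * np.pi) ** 1.5 * sz * syx**2
        # effect size: voxels within 1 sigma vs a 1.5-3 sigma shell
        d2 = ((zz - z0) / max(sz, 1e-6)) ** 2 + (
            ((yy - y0) ** 2 + (xx - x0) ** 2) / max(syx, 1e-6) ** 2
        )
        inner = patch[d2 <= 1.0]
        shell = patch[(d2 >= 1.5**2) & (d2 <= 3.0**2)]
        g = hedges_g(inner, shell)
        rows.append((z0 * vz, y0 * vy, x0 * vx, amp, foreground, g))
    return pd.DataFrame(
        rows, columns=["z", "y", "x", "amplitude", "foreground", "effect_size"]
    )


def effect_size_filter(
    detections: pd.DataFrame,
    thresholds: Mapping[str, float] = DEFAULT_EFFECT_SIZE_THRESHOLDS,
) -> pd.DataFrame:
    """Keep detections with effect_size ≥ the channel threshold (inclusive).

    Unknown channels raise; the operation is idempotent.
    """
    channels = detections["channel"].unique()
    unknown = [c for c in channels if c not in thresholds]
    if unknown:
        raise ValueError(f"unknown channel(s) {unknown}; thresholds known for {sorted(thresholds)}")
    thr = detections["channel"].map(thresholds).to_numpy(float)
    return detections[detections["effect_size"].to_numpy(float) >= thr]


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------


def bleach_correct(
    detections: pd.DataFrame,
    value_column: str = "foreground",
    reference_frame: int | None = None,
) -> pd.DataFrame:
    """Histogram-match per-frame intensities onto the first frame's distribution.

    Each frame's values are quantile-mapped onto the pooled distribution of
    the reference frame (the earliest frame by default), which removes any
    monotone per-frame intensity distortion — photobleaching in particular
    — while preserving the within-frame rank order exactly.  Frames with
    fewer than 3 detections are passed through unchanged and flagged in
    ``bleach_flag``.
    """
    det = detections.copy()
    frames = np.sort(det["frame"].unique())
    if frames.size < 2:
        raise ValueError("need at least 2 frames for bleach correction")
    ref_frame = frames[0] if reference_frame is None else reference_frame
    ref = np.sort(det.loc[det["frame"] == ref_frame, value_column].to_numpy(float))
    corrected = np.empty(len(det))
    flag = np.zeros(len(det), bool)
    for f in frames:
        m = (det["frame"] == f).to_numpy()
        vals = det.loc[m, value_column].to_numpy(float)
        if vals.size < 3:
            corrected[m] = vals
            flag[m] = True
            continue
        # empirical quantile of each value within its frame -> reference quantile
        q = (np.argsort(np.argsort(vals)) + 0.5) / vals.size
        corrected[m] = np.quantile(ref, q)
    det["corrected_intensity"] = corrected
    det["bleach_flag"] = flag
    return det


def bleach_safe_cutoff(
    counts: pd.DataFrame,
    q: float = 0.05,
    consecutive: int = 3,
) -> int:
    """Last frame before photobleaching measurably depresses focus counts.

    ``counts`` has columns ``frame, bin, median_count`` — the median focus
    number per spatial bin along the gonad.  Each frame's per-bin medians
    are compared with the first frame's by a paired Wilcoxon signed-rank
    test; p-values are Benjamini-Hochberg corrected across frames, and the
    cutoff is the last frame before the first run of ``consecutive``
    significant frames (guarding against isolated false positives).
    """
    piv = counts.pivot_table(index="bin", columns="frame", values="median_count")
    if piv.shape[0] < 5:
        raise ValueError("insufficient spatial bins (need >= 5)")
    frames = np.sort(piv.columns.to_numpy())
    ref = piv[frames[0]].to_numpy(float)
    pvals = []
    for f in frames[1:]:
        cur = piv[f].to_numpy(float)
        ok = np.isfinite(ref) & np.isfinite(cur)
        diff = cur[ok] - ref[ok]
        if np.allclose(diff, 0):
            pvals.append(1.0)
        else:
            pvals.append(wilcoxon(diff).pvalue)
    reject = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    run = 0
    for i, rej in enumerate(reject):
        run = run + 1 if rej else 0
        if run >= consecutive:
            first_bad = frames[1:][i - consecutive + 1]
            return int(first_bad - 1)
    return int(frames[-1])


# ---------------------------------------------------------------------------
# per-nucleus statistics
# ---------------------------------------------------------------------------


def count_stats(
    detections: pd.DataFrame,
    n_frames: int,
    channels: Iterable[str] | None = None,
    coloc_radius_um: float = 0.3,
) -> pd.DataFrame:
    """Per-nucleus mean/variance of focus counts and colocalized counts.

    Counts are over all analyzed frames (frames with zero detections count
    as zero).  When two channels are given, colocalization is scored per
    frame by mutual-nearest-neighbor matching within ``coloc_radius_um``.
    """
    if channels is None:
        channels = sorted(detections["channel"].unique())
    channels = list(channels)
    rows = []
    for nid, grp in detections.groupby("nucleus_id"):
        rec = {"nucleus_id": nid}
        for ch in channels:
            sub = grp[grp["channel"] == ch]
            counts = sub.groupby("frame").size().reindex(range(n_frames), fill_value=0)
            rec[f"mean_{ch}"] = float(counts.mean())
            rec[f"var_{ch}"] = float(counts.var(ddof=0))
        if len(channels) == 2:
            coloc = []
            for f in range(n_frames):
                a = grp[(grp["channel"] == channels[0]) & (grp["frame"] == f)]
                b = grp[(grp["channel"] == channels[1]) & (grp["frame"] == f)]
                coloc.append(_mutual_nn_count(a, b, coloc_radius_um))
            coloc = np.asarray(coloc, float)
            rec["mean_coloc"] = float(coloc.mean())
            rec["var_coloc"] = float(coloc.var(ddof=0))
        rows.append(rec)
    return pd.DataFrame(rows)


def _mutual_nn_count(a: pd.DataFrame, b: pd.DataFrame, radius: float) -> int:
    if a.empty or b.empty:
        return 0
    pa = a[["x", "y", "z"]].to_numpy(float)
    pb = b[["x", "y", "z"]].to_numpy(float)
    ta, tb = cKDTree(pa), cKDTree(pb)
    da, ia = tb.query(pa)
    db, ib = ta.query(pb)
    n = 0
    for i, (d, j) in enumerate(zip(da, ia)):
        if d <= radius and ib[j] == i:
            n += 1
    return n


def link_tracks(
    detections: pd.DataFrame,
    max_displacement_um: float = 2.0,
) -> pd.DataFrame:
    """Greedy nearest-neighbor frame-to-frame linking (plumbing).

    Adds a ``track_id`` column; a detection farther than
    ``max_displacement_um`` from every track head starts a new track.
    """
    det = detections.sort_values("frame").copy()
    track_id = np.full(len(det), -1, dtype=int)
    heads: list[tuple[np.ndarray, int]] = []  # (last position, track id)
    next_id = 0
    idx = det.index.to_numpy()
    pos_all = det[["x", "y", "z"]].to_numpy(float)
    frame_all = det["frame"].to_numpy()
    row_of = {ix: k for k, ix in enumerate(idx)}
    for f in np.sort(det["frame"].unique()):
        rows = [row_of[ix] for ix in idx[frame_all == f]]
        used = set()
        # greedy by ascending distance
        cand = []
        for r in rows:
            for h, (hp, hid) in enumerate(heads):
                d = np.linalg.norm(pos_all[r] - hp)
                if d <= max_displacement_um:
                    cand.append((d, r, h))
        for d, r, h in sorted(cand):
            if track_id[r] != -1 or h in used:
                continue
            track_id[r] = heads[h][1]
            heads[h] = (pos_all[r], heads[h][1])
            used.add(h)
        for r in rows:
            if track_id[r] == -1:
                track_id[r] = next_id
                heads.append((pos_all[r], next_id))
                next_id += 1
    det["track_id"] = track_id
    return det
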