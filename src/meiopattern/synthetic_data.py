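"""Synthetic germline imaging data with known ground truth.

Generators for the four kinds of input the analysis pipeline consumes:

* time-lapse nucleus tracks + focus detection tables for a gonad in which
  nuclei advance row-wise toward late pachytene (``gen_germline_movie``),
* 3D synaptonemal-complex (SC) polyline traces with persistent/blinking
  focus placements (``gen_sc_traces``),
* dual-channel SMLM localization tables for recombination nodules lying on
  a pair of chromosome axes (``gen_smlm_nodule``),
* folded focus-position samples emulating chromosome-spread data
  (``gen_spread_foci``).

Every generator is deterministic given a seed, and emits ground-truth
labels so recovery by the downstream estimators can be scored exactly.

Model choices
-------------
Blinking foci follow a two-state discrete-time telegraph process with
per-frame switching probabilities (on/off dwell times are free parameters;
the biology constrains them only to the minute scale).  Persistent foci are
present in every frame.  Focus intensity is the product of a
cumulative-Gaussian nucleus-level ramp (the mid-to-late-pachytene
transition), an exponential per-frame photobleaching factor and mean-one
multiplicative lognormal noise, so the expected intensity at frame ``f``
of a nucleus in row ``r`` is exactly ``ramp(r) * 2**(-f / halflife)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GermlineConfig",
    "FocusKineticsConfig",
    "NoduleGroundTruth",
    "gen_germline_movie",
    "gen_sc_traces",
    "gen_trace_movie_detections",
    "gen_smlm_nodule",
    "gen_spread_foci",
    "sample_arm_biased",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class GermlineConfig:
    """Geometry and kinetics of the simulated gonad.

    ``intensity_ramp`` is (midpoint row, width in rows, low level, high
    level) of the cumulative-Gaussian focus-intensity profile that marks
    late-pachytene entry.  ``transit_h_per_row`` defaults to the measured
    1.1 h per row of nuclear movement.
    """

    n_rows: int = 30
    nuclei_per_row: int = 4
    row_spacing_um: float = 4.0
    transit_h_per_row: float = 1.1
    onset_row: float = 20.0
    intensity_ramp: tuple[float, float, float, float] = (20.0, 2.0, 1.0, 4.0)
    bleach_halflife_frames: float = 30.0
    frame_interval_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.nuclei_per_row < 1:
            raise ValueError("counts must be >= 1")
        if not (1 <= self.onset_row <= self.n_rows):
            raise ValueError("onset_row must lie within [1, n_rows]")
        if self.intensity_ramp[1] <= 0:
            raise ValueError("intensity ramp width must be positive")
        if self.row_spacing_um <= 0 or self.transit_h_per_row <= 0:
            raise ValueError("row spacing and transit must be positive")

    def ramp(self, row: np.ndarray | float) -> np.ndarray | float:
        """Expected nucleus-level focus intensity at a (continuous) row."""
        from scipy.stats import norm

        mid, width, low, high = self.intensity_ramp
        return low + (high - low) * norm.cdf((np.asarray(row, float) - mid) / width)

    def bleach(self, frame: np.ndarray | float) -> np.ndarray | float:
        return 2.0 ** (-np.asarray(frame, float) / self.bleach_halflife_frames)


@dataclass
class FocusKineticsConfig:
    """Per-chromosome focus placement and blinking kinetics.

    ``persistent_per_chromosome`` fixes the number of stable foci per SC;
    set it to ``None`` to place persistent foci with gamma-distributed gaps
    (shape ``persistent_gamma_shape``, mean gap ``persistent_mean_gap_frac``
    of chromosome length, per-chromosome count drawn from
    ``persistent_count_probs``) instead, which is the configuration used to
    emulate interference-patterned spacing.  Blinking site counts are
    Poisson with mean ``n_blinking_sites_per_chromosome``, so they show no
    interference.
    """

    n_chromosome_pairs: int = 6
    persistent_per_chromosome: Optional[int] = 1
    persistent_gamma_shape: float = 4.6
    persistent_mean_gap_frac: float = 0.3
    # during mid-pachytene each chromosome pair carries 1 or 2 persistent foci
    persistent_count_probs: tuple = ((1, 0.5), (2, 0.5))
    blinking_rate_on: float = 0.15
    blinking_rate_off: float = 0.25
    n_blinking_sites_per_chromosome: int = 3
    blink_position_distribution: str = "uniform"
    persistent_position_distribution: str = "uniform"
    arm_bias_quantile: tuple[float, float] = (0.9, 0.33)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosome_pairs < 1:
            raise ValueError("need at least one chromosome pair")
        for p in (self.blinking_rate_on, self.blinking_rate_off):
            if not (0.0 <= p <= 1.0):
                raise ValueError("blinking rates are per-frame probabilities in [0, 1]")
        if self.persistent_gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        frac, cutoff = self.arm_bias_quantile
        if not (0.0 < cutoff <= 0.5) or not (0.0 <= frac <= 1.0):
            raise ValueError("arm_bias_quantile must be (fraction, cutoff in (0, 0.5])")
        if self.blink_position_distribution not in ("uniform", "arm_biased"):
            raise ValueError(f"unknown distribution {self.blink_position_distribution!r}")
        if self.persistent_position_distribution not in ("uniform", "arm_biased"):
            raise ValueError(f"unknown distribution {self.persistent_position_distribution!r}")

    @property
    def blink_duty_cycle(self) -> float:
        s = self.blinking_rate_on + self.blinking_rate_off
        return 0.0 if s == 0 else self.blinking_rate_on / s


@dataclass
class NoduleGroundTruth:
    """One simulated recombination nodule for the SMLM branch.

    A "doublet" is a ring (3D-rotated ellipse with major/minor spans ``a``
    and ``b``) spanning both chromosome axes; a "singlet" is a compact blob
    sitting on a single axis strand.
    """

    kind: str = "doublet"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    a: float = 150.0
    b: float = 80.0
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_separation: float = 150.0
    n_localizations: int = 300
    precision_xy: float = 10.0
    precision_z: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("singlet", "doublet"):
            raise ValueError("kind must be 'singlet' or 'doublet'")
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")
        if self.precision_xy <= 0 or self.precision_z <= 0:
            raise ValueError("precisions must be positive")
        if self.n_localizations < 20:
            raise ValueError("need at least 20 localizations")


# ---------------------------------------------------------------------------
# folded-position presets
# ---------------------------------------------------------------------------


def sample_arm_biased(
    rng,
    n: int,
    frac_within: float = 0.9,
    cutoff: float = 0.33,
) -> np.ndarray:
    """Folded positions in [0, 0.5] with ``frac_within`` of mass below ``cutoff``.

    Two-component mixture: a Beta(1.5, 1.5)-shaped arm component scaled to
    [0, cutoff] and a uniform center component on (cutoff, 0.5].  The
    mixture weight equals the requested quantile exactly, so the preset is
    calibrated by construction.
    """
    rng = _as_rng(rng)
    arm = rng.random(n) < frac_within
    out = np.empty(n)
    out[arm] = cutoff * rng.beta(1.5, 1.5, size=int(arm.sum()))
    out[~arm] = cutoff + (0.5 - cutoff) * rng.random(int((~arm).sum()))
    return out


_SPREAD_PRESETS: dict[str, Callable[[np.random.Generator, int], np.ndarray]] = {
    "uniform": lambda rng, n: 0.5 * rng.random(n),
    "arm_biased_late_CO": lambda rng, n: sample_arm_biased(rng, n, 0.9, 0.33),
}


def gen_spread_foci(preset: str, n: int, rng=None) -> np.ndarray:
    """Draw ``n`` folded focus positions in [0, 0.5] from a named preset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        sampler = _SPREAD_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(_SPREAD_PRESETS)}"
        ) from None
    return sampler(_as_rng(rng), n)


def _sample_position_frac(rng: np.random.Generator, dist: str, n: int,
                          quantile: tuple[float, float]) -> np.ndarray:
    """Positions along the full chromosome as a fraction of length in [0, 1]."""
    if dist == "uniform":
        return rng.random(n)
    folded = sample_arm_biased(rng, n, quantile[0], quantile[1])
    # unfold: either arm with equal probability
    flip = rng.random(n) < 0.5
    return np.where(flip, 1.0 - folded, folded)


# ---------------------------------------------------------------------------
# germline movie
# ---------------------------------------------------------------------------


def _telegraph(rng: np.random.Generator, n_frames: int, p_on: float, p_off: float) -> np.ndarray:
    """Boolean on/off series of a discrete-time two-state telegraph process."""
    state = np.empty(n_frames, dtype=bool)
    duty = 0.0 if p_on + p_off == 0 else p_on / (p_on + p_off)
    state[0] = rng.random() < duty
    for f in range(1, n_frames):
        if state[f - 1]:
            state[f] = rng.random() >= p_off
        else:
            state[f] = rng.random() < p_on
    return state


def _lognoise(rng: np.random.Generator, n: int, sigma: float = 0.2) -> np.ndarray:
    """Mean-one multiplicative lognormal noise."""
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def gen_germline_movie(
    cfg: GermlineConfig,
    kin: FocusKineticsConfig,
    n_frames: int = 40,
    position_noise_um: float = 0.1,
    rng=None,
):
    """Simulate a time-lapse movie of nuclei advancing through the gonad.

    Returns ``(tracks, detections, truth)`` DataFrames.  ``tracks`` holds
    per-frame centroids, volume and sphericity; ``detections`` the per-frame
    focus table (frame, nucleus_id, channel, x/y/z µm, amplitude,
    foreground, effect_size); ``truth`` one row per focus with its class
    and arc position.

    Nuclei advance one row per ``cfg.transit_h_per_row`` along +x, so a
    nucleus displaces ``t_min / (60 * transit)`` rows in ``t_min`` minutes.
    """
    rng = _as_rng(rng if rng is not None else cfg.seed)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n_nuclei = cfg.n_rows * cfg.nuclei_per_row
    if n_nuclei < 1:
        raise ValueError("degenerate config: no nuclei")

    frames = np.arange(n_frames)
    t_hours = frames * cfg.frame_interval_min / 60.0
    drows = t_hours / cfg.transit_h_per_row  # rows advanced per frame
    speed_um_per_h = cfg.row_spacing_um / cfg.transit_h_per_row

    track_rows, det_rows, truth_rows = [], [], []
    for row in range(1, cfg.n_rows + 1):
        for j in range(cfg.nuclei_per_row):
            nid = (row - 1) * cfg.nuclei_per_row + j
            x0 = row * cfg.row_spacing_um + rng.normal(0, 0.15)
            y0 = j * cfg.row_spacing_um + rng.normal(0, 0.15)
            z0 = rng.normal(0, 0.3)
            diameter = rng.uniform(4.5, 6.5)
            volume = np.pi / 6.0 * diameter**3
            sphericity = rng.uniform(0.85, 0.98)

            xs = x0 + speed_um_per_h * t_hours + rng.normal(0, position_noise_um, n_frames)
            ys = y0 + rng.normal(0, position_noise_um, n_frames)
            zs = z0 + rng.normal(0, position_noise_um, n_frames)
            for f in frames:
                track_rows.append((f, nid, xs[f], ys[f], zs[f], volume, sphericity))

            # focus complement of this nucleus
            foci = []
            n_pers = kin.persistent_per_chromosome
            n_pers = 1 if n_pers is None else n_pers
            for chrom in range(kin.n_chromosome_pairs):
                fr = _sample_position_frac(
                    rng, kin.persistent_position_distribution, n_pers, kin.arm_bias_quantile
                )
                for arc in fr:
                    foci.append(("persistent", chrom, float(arc), np.ones(n_frames, bool)))
                n_sites = int(rng.poisson(kin.n_blinking_sites_per_chromosome))
                fb = _sample_position_frac(
                    rng, kin.blink_position_distribution, n_sites, kin.arm_bias_quantile,
                )
                for arc in fb:
                    on = _telegraph(rng, n_frames, kin.blinking_rate_on, kin.blinking_rate_off)
                    if on.any():
                        foci.append(("blinking", chrom, float(arc), on))

            for k, (label, chrom, arc, on) in enumerate(foci):
                fid = nid * 1000 + k
                truth_rows.append((fid, nid, chrom, label, arc))
                # focus offset inside the nucleus, fixed over time
                off = rng.normal(0, diameter / 6.0, size=3)
                rows_f = row + drows
                base = np.asarray(cfg.ramp(rows_f)) * np.asarray(cfg.bleach(frames))
                amp = base * _lognoise(rng, n_frames)
                fg = base * _lognoise(rng, n_frames)
                g = rng.normal(5.0, 0.8, n_frames)
                for f in frames[on]:
                    det_rows.append(
                        (f, nid, "cosa1", xs[f] + off[0], ys[f] + off[1], zs[f] + off[2],
                         amp[f], fg[f], g[f])
                    )

    tracks = pd.DataFrame(
        track_rows, columns=["frame", "nucleus_id", "x", "y", "z", "volume", "sphericity"]
    )
    detections = pd.DataFrame(
        det_rows,
        columns=["frame", "nucleus_id", "channel", "x", "y", "z",
                 "amplitude", "foreground", "effect_size"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["focus_id", "nucleus_id", "chromosome", "label", "arc_frac"]
    )
    return tracks, detections, truth


# ---------------------------------------------------------------------------
# SC traces and focus placements
# ---------------------------------------------------------------------------


def _random_space_curve(rng: np.random.Generator, length_um: float,
                        start: np.ndarray | None = None,
                        n_segments: int = 60, wiggle: float = 0.05,
                        dir_noise: float = 0.1) -> np.ndarray:
    """Smooth open 3D polyline of total chord length ``length_um``.

    Built by integrating a slowly varying unit direction field around a
    common base direction; the small per-step rotations keep curvature low
    so the curve does not self-intersect at the scales used here.
    """
    step = length_um / n_segments
    v = np.array([1.0, 0.0, 0.0]) + rng.normal(scale=dir_noise, size=3)
    v /= np.linalg.norm(v)
    if start is None:
        start = rng.uniform(-5, 5, size=3)
    pts = [np.asarray(start, float)]
    for _ in range(n_segments):
        dv = rng.normal(scale=wiggle, size=3)
        v = v + dv
        v /= np.linalg.norm(v)
        pts.append(pts[-1] + step * v)
    return np.asarray(pts)


def _min_curve_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def _place_separated_curve(rng: np.random.Generator, length_um: float,
                           start: np.ndarray, slot_y: float,
                           slab_half_um: float = 0.9,
                           n_tries: int = 60) -> np.ndarray:
    """Draw a curve confined to its own transverse slab.

    Chromosomes are laid out in parallel slabs 3 µm apart; keeping every
    curve within ``slab_half_um`` of its slot guarantees > 1 µm clearance
    between traces, so nearest-trace focus assignment is unambiguous —
    mirroring the analyzed chromosomes (traces whose geometry prevented
    reliable assignment were excluded from the real analysis).
    """
    wiggle, dir_noise = 0.05, 0.08
    for attempt in range(n_tries):
        cand = _random_space_curve(rng, length_um, start=start,
                                   wiggle=wiggle, dir_noise=dir_noise)
        if np.max(np.abs(cand[:, 1] - slot_y)) <= slab_half_um:
            return cand
        if attempt % 5 == 4:
            # straighten until the curve is guaranteed to stay in its slab
            wiggle *= 0.5
            dir_noise *= 0.5
    raise RuntimeError("could not confine a trace to its slab")


def _gamma_spacing_positions(
    rng: np.random.Generator,
    shape: float,
    mean_gap: float,
    count_probs: Sequence[tuple[int, float]],
) -> np.ndarray:
    """Gamma-spaced positions on [0, 1] (normalized arc coordinate).

    The focus count is drawn first, then the inter-focus gaps as i.i.d.
    Gamma(shape) variates with the requested mean, re-drawn in the rare
    case they do not fit the chromosome; the block of foci is placed
    uniformly.  Drawing the count first (rather than running an open-ended
    renewal and discarding points beyond the end) keeps the retained
    adjacent gaps exactly gamma-distributed instead of size-biased by
    right-censoring.
    """
    ks = np.array([k for k, _ in count_probs])
    ps = np.array([p for _, p in count_probs], float)
    k = int(rng.choice(ks, p=ps / ps.sum()))
    if k == 0:
        return np.empty(0)
    if k == 1:
        return rng.random(1)
    scale = mean_gap / shape
    for _ in range(1000):
        gaps = rng.gamma(shape, scale, size=k - 1)
        total = gaps.sum()
        if total < 1.0:
            start = rng.random() * (1.0 - total)
            return start + np.concatenate([[0.0], np.cumsum(gaps)])
    raise RuntimeError("gamma gaps never fit the chromosome; lower the mean gap")


def gen_sc_traces(
    kin: FocusKineticsConfig,
    n_nuclei: int = 1,
    chromosome_length_um: Callable[[np.random.Generator], float] | None = None,
    include_x: bool = False,
    rng=None,
):
    """Generate per-nucleus SC polylines plus a focus placement table.

    Returns ``(traces, placements)``.  ``traces`` is a list of dicts with
    keys ``trace_id, nucleus_id, points (N×3 µm), length_um, is_X``;
    ``placements`` is a DataFrame with one row per placed focus
    (focus_id, nucleus_id, trace_id, label, arc_um, arc_frac).

    Persistent foci are placed either at a fixed count per chromosome
    (positions from ``persistent_position_distribution``) or, when
    ``persistent_per_chromosome is None``, by a gamma-renewal process whose
    normalized gaps are Gamma(``persistent_gamma_shape``) distributed —
    the interference-patterned configuration.  Blinking sites come from
    ``blink_position_distribution``.
    """
    rng = _as_rng(rng if rng is not None else kin.seed)
    if chromosome_length_um is None:
        chromosome_length_um = lambda r: r.uniform(4.0, 7.0)

    traces, rows = [], []
    tid = 0
    fid = 0
    for nid in range(n_nuclei):
        origin = np.array([0.0, 0.0, 20.0 * nid])  # one region per nucleus
        for chrom in range(kin.n_chromosome_pairs):
            is_x = include_x and chrom == kin.n_chromosome_pairs - 1
            L = float(chromosome_length_um(rng))
            if L <= 1.0:
                raise ValueError("chromosome length must exceed 1 µm")
            if is_x:
                L *= 0.6  # the X pair is notably shorter
            slot_y = 3.0 * chrom
            start = origin + np.array([rng.uniform(-1, 1),
                                       slot_y + rng.uniform(-0.2, 0.2),
                                       rng.uniform(-0.5, 0.5)])
            pts = _place_separated_curve(rng, L, start, origin[1] + slot_y)
            traces.append(
                {"trace_id": tid, "nucleus_id": nid, "points": pts,
                 "length_um": L, "is_X": bool(is_x)}
            )
            if kin.persistent_per_chromosome is None:
                frac = _gamma_spacing_positions(
                    rng, kin.persistent_gamma_shape, kin.persistent_mean_gap_frac,
                    kin.persistent_count_probs,
                )
            else:
                frac = np.sort(_sample_position_frac(
                    rng, kin.persistent_position_distribution,
                    kin.persistent_per_chromosome, kin.arm_bias_quantile,
                ))
            for a in frac:
                rows.append((fid, nid, tid, "persistent", float(a) * L, float(a)))
                fid += 1
            n_sites = int(rng.poisson(kin.n_blinking_sites_per_chromosome))
            fb = _sample_position_frac(
                rng, kin.blink_position_distribution, n_sites, kin.arm_bias_quantile,
            )
            for a in fb:
                rows.append((fid, nid, tid, "blinking", float(a) * L, float(a)))
                fid += 1
            tid += 1

    placements = pd.DataFrame(
        rows, columns=["focus_id", "nucleus_id", "trace_id", "label", "arc_um", "arc_frac"]
    )
    return traces, placements


def gen_trace_movie_detections(
    traces: Sequence[dict],
    placements: pd.DataFrame,
    kin: FocusKineticsConfig,
    n_frames: int = 40,
    jitter_um: float = 0.05,
    rng=None,
) -> pd.DataFrame:
    """Per-frame 3D focus detections for traced nuclei.

    Persistent placements are detected in every frame; blinking placements
    toggle by the telegraph process.  Detected positions are the trace
    point at the placed arc position plus isotropic Gaussian jitter.
    Columns: frame, nucleus_id, focus_id, channel, x, y, z, amplitude,
    foreground, effect_size, label (ground truth carried along).
    """
    rng = _as_rng(rng if rng is not None else kin.seed)
    by_id = {t["trace_id"]: t for t in traces}
    rows = []
    for rec in placements.itertuples(index=False):
        tr = by_id[rec.trace_id]
        pts = tr["points"]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        pos = np.array([np.interp(rec.arc_um, cum, pts[:, i]) for i in range(3)])
        if rec.label == "persistent":
            on = np.ones(n_frames, bool)
        else:
            on = _telegraph(rng, n_frames, kin.blinking_rate_on, kin.blinking_rate_off)
        amp = _lognoise(rng, n_frames)
        for f in np.nonzero(on)[0]:
            p = pos + rng.normal(0, jitter_um, 3)
            rows.append((int(f), rec.nucleus_id, rec.focus_id, "cosa1",
                         p[0], p[1], p[2], amp[f], amp[f], 5.0, rec.label))
    return pd.DataFrame(
        rows, columns=["frame", "nucleus_id", "focus_id", "channel",
                       "x", "y", "z", "amplitude", "foreground", "effect_size", "label"]
    )


# ---------------------------------------------------------------------------
# SMLM nodules
# ---------------------------------------------------------------------------


def _rotation_matrix(angles: Sequence[float]) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", angles).as_matrix()


def _ellipse_perimeter_points(a: float, b: float, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Points uniform in arc length along the ellipse x=a cos t, y=b sin t."""
    t_dense = np.linspace(0, 2 * np.pi, 4096)
    dx = np.hypot(-a * np.sin(t_dense), b * np.cos(t_dense))
    arc = np.concatenate([[0.0], np.cumsum(0.5 * (dx[1:] + dx[:-1]) * np.diff(t_dense))])
    s = rng.random(n) * arc[-1]
    t = np.interp(s, arc, t_dense)
    return np.column_stack([a * np.cos(t), b * np.sin(t), np.zeros(n)])


def gen_smlm_nodule(gt: NoduleGroundTruth, n_axis_localizations: int = 2000,
                    axis_length_nm: float = 1500.0, rng=None):
    """Simulate one SMLM field: a nodule cluster plus two axis strands.

    Returns ``(nodule, axis)`` localization DataFrames with columns
    x, y, z (nm), precision_xy, precision_z, channel.  The two axis strands
    run along x, separated by ``gt.axis_separation`` in y and centred on
    the nodule center.  Doublets are rings sampled uniformly along the
    rotated ellipse perimeter; singlets are compact blobs on one strand.
    """
    rng = _as_rng(rng)
    c = np.asarray(gt.center, float)
    noise = np.array([gt.precision_xy, gt.precision_xy, gt.precision_z])

    if gt.kind == "doublet":
        pts = _ellipse_perimeter_points(gt.a, gt.b, gt.n_localizations, rng)
        pts = pts @ _rotation_matrix(gt.rotation).T + c
    else:
        # compact blob sitting on one strand (at +sep/2 in y)
        blob_sigma = 25.0
        center = c + np.array([0.0, gt.axis_separation / 2.0, 0.0])
        pts = center + rng.normal(0, blob_sigma, size=(gt.n_localizations, 3))
    pts = pts + rng.normal(size=pts.shape) * noise

    nodule = pd.DataFrame(pts, columns=["x", "y", "z"])
    nodule["precision_xy"] = gt.precision_xy
    nodule["precision_z"] = gt.precision_z
    nodule["channel"] = "nodule"

    half = n_axis_localizations // 2
    ax_rows = []
    for sign in (+1, -1):
        xs = c[0] + (rng.random(half) - 0.5) * axis_length_nm
        ys = np.full(half, c[1] + sign * gt.axis_separation / 2.0)
        zs = np.full(half, c[2])
        p = np.column_stack([xs, ys, zs]) + rng.normal(size=(half, 3)) * noise
        ax_rows.append(p)
    axis = pd.DataFrame(np.vstack(ax_rows), columns=["x", "y", "z"])
    axis["precision_xy"] = gt.precision_xy
    axis["precision_z"] = gt.precision_z
    axis["channel"] = "axis"
    return nodule, axis
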