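# Methods

This note documents the models, parameters and design choices behind
`meiopattern`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
what the synthetic validation does and does not show.

## Pseudotime staging of germline nuclei

Nuclei in the *C. elegans* gonad form a conveyor belt: meiotic stage is a
monotone function of position.  Staging proceeds in four steps.

1. **Rotation.** Centroids are centered and rotated onto their principal
   axes (SVD, determinant forced to +1 so the map is rigid).  Requires ≥ 3
   non-collinear centroids.
2. **Centerline.** The transverse coordinates are LOWESS-smoothed against
   the progression coordinate (smoothing fraction 0.3 of points by
   default; the smoother is standard, the span is our choice — small
   enough to follow a curved gonad, large enough to average over one row
   of nuclei).  Positions are arc lengths at the foot point of each
   centroid on a 2048-point discretization of the centerline; foot points
   at the domain boundary are flagged as clamped.
3. **Onset.** Late-pachytene entry is the inflection point of a
   4-parameter cumulative Gaussian fitted by least squares to the
   nucleus-level log median focus amplitude versus position.  The fit is
   multi-started from 5 initial midpoints (position quantiles 0.15–0.85)
   with the width bounded positive; a fit that does not improve on a flat
   profile, or whose midpoint falls outside the observed range, is
   rejected as "no transition".  Amplitudes are normalized by their global
   median before taking logs; any monotone normalization gives the same
   inflection point, so the choice is inconsequential and documented here
   only for reproducibility.
4. **Units.** Positions are divided by the row spacing — the **median**
   nearest-neighbor centroid distance, median rather than mean for
   robustness to segmentation gaps — and multiplied by the per-row transit
   time (default 1.1 h/row) to give hours to onset.  Positions are
   negative before onset and zero at onset.

The transit time itself is estimated from per-nucleus linear fits of
position versus imaging time; the per-nucleus slopes (µm/h) are converted
to h/row and averaged.  Stationary nuclei are flagged and excluded.

## Focus detection and dynamics

The spot detector (Laplacian-of-Gaussian candidates refined by a 3D
Gaussian fit) is plumbing: the quantities that matter downstream are the
fitted amplitude, the foreground integral, and a Hedges'-g effect size
computed between the voxels within 1σ of the fit center and a 1.5–3σ
background shell (small-sample-corrected standardized mean difference).
Detections below the per-channel effect-size threshold (1.1 for
HaloTag::COSA-1, 2.1 for MSH-5::HaloTag, 3.0 for COSA-1::mNeonGreen) are
discarded; the bound is inclusive.

**Photobleaching** is corrected by histogram matching: each frame's
foreground values are quantile-mapped onto the pooled first-frame
distribution.  The map is monotone, so within-frame rank order is
preserved exactly — an invariant the tests check.  Matching pools
detections across nuclei by default (a per-nucleus variant would need many
detections per nucleus per frame to be stable); frames with fewer than 3
detections pass through flagged.

**Bleach-safe window.** Counts are binned along the gonad; each frame's
per-bin median counts are compared with frame 1 by a paired Wilcoxon
signed-rank test, BH-corrected across frames at q = 0.05.  The cutoff is
the last frame before the first run of 3 consecutive significant frames —
the run requirement guards against isolated false positives and is our
choice; the test itself is standard.

Colocalization between channels uses mutual nearest neighbors within
0.3 µm (≈ one PSF width); the radius is a documented free parameter.
Frame-to-frame linking is a greedy nearest-neighbor linker with a 2 µm
maximum displacement — deliberately simple plumbing, not a tracking
contribution.

## Trace mapping and persistent/blinking classification

SC polylines are smoothed with a cubic spline and resampled at equidistant
arc length (120 nm).  Focus detections are snapped to the nearest
resampled point over all traces (ties break to the lower trace id;
detections farther than 0.75 µm from every trace are unassigned).  Around
each assigned arc position an interval of half-width
`w(φ) = √((r_xy cos φ)² + (r_z sin φ)²)` is built, where φ is the local
tangent elevation against the imaging plane and r_xy = 250 nm,
r_z = 600 nm are confocal resolution limits (configurable).  Intervals
that transitively overlap across frames form one focus group.

A group is **persistent** when detected in at least 95% of analyzed
frames (2 missed detections in a 40-frame window), otherwise **blinking**;
a blinking group needs ≥ 2 detections to count at all.  The 95% rule and
the 2-detection minimum quantify a distinction that was qualitative in the
underlying imaging ("remains marked throughout" versus "repeatedly
disappears and reappears"); both are parameters.  Per-frame intensity
series carry zeros for undetected frames, which is what the
neighbor-correlation analysis consumes.

Traces running steeply along the optical axis cannot be tracked reliably;
a trace is excluded when more than 20% of its arc length has tangent
elevation above 60°, and the X chromosome (markedly shorter) is always
excluded.  This quantitative rule is an automatic proxy for what is a
manual exclusion when working with real movies.

## Arm bias and interference

Folding maps an arc position s on a chromosome of length L to
`min(s, L−s)/L ∈ [0, 0.5]`.  Systematic offsets between acquisition
modalities (live versus spread) are corrected additively by the median
difference of a shared reference population; the shift is recorded.
Distribution pairs are compared with the 1-D Wasserstein distance and
two-sample KS tests, BH-adjusted across pairs.  The arm/center split uses
a 0.33 length-fraction boundary in a 2×2 Fisher's exact test.

**Gamma shape.**  Adjacent inter-focus distances from chromosomes with
≥ 2 foci are pooled after normalizing by chromosome length (normalization
avoids mixing length scales across chromosomes; a raw-distance mode is
available).  The fit is the two-parameter gamma MLE with location fixed at
zero; the shape CI is a seeded 1000-resample bootstrap.  γ = 1 is the
Poisson calibration point, which the tests verify, along with monotone
recovery of γ = 1 < 4.6 < 40.  Near-constant distances make the MLE
diverge; such fits are reported degenerate with the shape capped at 1000.

**Normalized interference length.**  For a stationary point process with
pair correlation suppressed over half-length ℓ, the count variance on a
chromosome of length L is depressed below Poisson:
`Var(N) ≈ E(N) − 2ρ²Lℓ` with ρ = E(N)/L, giving
`ℓ = L(E[N] − Var[N]) / (2E[N]²)`.  Normalizing by the maximum possible
exclusion L/2 yields

    L̂int = (mean(N) − var(N)) / mean(N)²,

clipped to [0, 1] (negative values indicate clustering, not
interference).  The statistic is 0 under Poisson placement, 1 when every
chromosome carries exactly one focus, and — unlike the gamma fit — uses
chromosomes with 0 or 1 foci.  It depends on counts only, so it is
invariant to relabeling and rescaling.  Variance uses ddof = 1 so the
Poisson null is unbiased at small chromosome numbers.  Per-nucleus values
(6 counts each) are noisy by construction; comparisons between populations
therefore use the Mann-Whitney test across nuclei.

**Neighbor-intensity correlation.**  Each focus is paired once with its
nearest neighbor (greedy by ascending distance, 1-D along the trace or
3-D within the nucleus); Pearson's r pools the per-frame intensity pairs
across all pairs, with zeros in undetected frames.  A negative r is the
signature of material redistribution between neighboring foci predicted
by coarsening models.

## SMLM recombination nodules

Localizations are kept for z ∈ [−300, 300] nm, lateral precision ≤ 15 nm
and axial precision ≤ 25 nm (bounds inclusive).  The chromosome-axis
**midline** is a principal-curve estimate: localizations are projected
onto the cloud's principal direction and averaged in 150 nm windows
(75 nm step); a per-window 1-D 2-means split on the principal transverse
coordinate yields the two strand curves and their separation.  A median
separation below 40 nm flags the strands as unresolved.  The construction
is our contract for a step that is unspecified in the underlying imaging
protocol, validated only against synthetic ground truth.

Candidate nodules are DBSCAN clusters (ε = 100 nm, 20 points for a core,
counting the point itself) of the nodule-channel localizations within
350 nm of the midline; clusters are retained when their center lies
within 120 nm of it, and members within a 400 nm square ROI are attached.
The tests verify sklearn's clustering against a hand-written brute-force
density-reachability enumeration on small instances.

**Elliptical model fit.**  The model is uniform density along the
perimeter of a 3D-rotated ellipse (spans a ≥ b), discretized at 64
arc-length-uniform points, convolved per localization with an anisotropic
Gaussian at that localization's own precisions, plus a flat background
over the ROI (weight initialized at 0.1).  The likelihood is maximized
over center (3), log-spans (2), three Euler angles and the logit
background weight by Nelder-Mead simplex from 8 in-plane rotation starts
(coarse pass, 250 iterations each) followed by one long polish
(fatol 1e-8).  The fit is initialized at the median localization
coordinates with spans from the cluster covariance.  Perimeters use
Ramanujan's second approximation (relative error < 1e-4 for a/b ≤ 5,
verified against quadrature).  A fit is **degenerate** when it fails to
converge, the minor span collapses below 40 nm (the ring is describing a
blob at the localization-precision scale), or a/b > 6; degenerate fits
are excluded from perimeter comparisons but the cluster is retained.

**Axis contact.**  A strand is contacted when ≥ 10% of the cluster's
localizations (and ≥ 5) lie within 90 nm of its curve; both strands →
doublet-like "both_axes", one → "one_axis", neither or unresolved strands
→ "unclear".  This rule automates what is a manual classification on real
images, and is validated on generator ground truth only.  Perimeter
distributions between classes are compared by Kruskal-Wallis followed by
BH-adjusted pairwise rank-sum tests.

## Axis coverage and count profiles

Marker coverage of the chromosome axis is computed per nucleus: both
channels are Otsu-thresholded within the nucleus mask and coverage is
|marker⁺ ∩ axis⁺| / |axis⁺|.  Per-nucleus thresholding makes the measure
invariant to affine intensity rescaling and to staining variability
between nuclei; a global-threshold option exists.  Focus-count profiles
along the gonad are position-sorted per-nucleus counts with a 10-nucleus
rolling median (a presentation choice).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for every label, and is itself under test.

* **Germline movie.**  Nuclei sit on a row grid (default 30 rows × 7
  nuclei, 4 µm spacing) and advance at 1.1 h/row; frames are 1 min apart.
  Focus intensity is `ramp(row) × 2^(−frame/halflife) × ε` with a
  cumulative-Gaussian ramp (midpoint row 20, width 2 rows, 4-fold
  amplitude step), a 30-frame bleach half-life, and mean-one lognormal
  noise ε (σ = 0.2), so the expected intensity factorizes exactly — a
  property verified by Monte-Carlo averaging.
* **Blinking** is a two-state discrete-time telegraph process with
  per-frame switching probabilities (defaults 0.15 on, 0.25 off, i.e.
  minute-scale dwell times with duty cycle 0.375).  The imaging literature
  constrains these only to "minutes"; they are free, documented
  parameters.  Blinking-site counts per chromosome are Poisson (mean 3),
  so blinking foci carry no count-interference signal.
* **SC traces** are slowly-wiggling space curves (4–7 µm arc length,
  uniform) laid out in parallel slabs 3 µm apart, each curve confined to
  ±0.9 µm of its slab center.  The confinement guarantees > 1 µm
  clearance between traces, so nearest-trace assignment is unambiguous —
  the synthetic analogue of restricting the real analysis to traces whose
  geometry permits reliable tracking.  The optional X-chromosome pair is
  generated 40% shorter and flagged.
* **Persistent placement** uses either a fixed count per chromosome or,
  for interference emulation, gamma-distributed gaps: the per-chromosome
  focus count is drawn first (1 or 2 with equal probability, matching the
  observed mid-pachytene counts), then the inter-focus gaps as i.i.d.
  Gamma(shape 4.6, mean 0.3 of chromosome length) variates, re-drawn in
  the rare case they exceed the chromosome, and the block is placed
  uniformly.  Drawing the count first keeps the retained gaps exactly
  gamma-distributed; an open-ended renewal process truncated at the
  chromosome end would size-bias the retained gaps downward and corrupt
  shape recovery.  A KS goodness-of-fit test on 10⁴ pooled gaps verifies
  the construction.
* **Arm-biased folded positions** are a two-component mixture: with
  probability 0.9 a Beta(1.5, 1.5) draw scaled to [0, 0.33], otherwise
  uniform on (0.33, 0.5].  The mixture weight *is* the arm-bias quantile,
  so the preset is calibrated by construction, with binomial fluctuation
  at finite n.
* **SMLM nodules.**  Doublets sample localizations uniformly along the
  rotated ellipse perimeter; singlets are isotropic 25 nm blobs on one
  axis strand; axis strands are parallel lines at the configured
  separation (150 nm default).  All localizations get Gaussian noise at
  their stated anisotropic precisions and carry precision columns.

**What the synthetic validation does not show.**  The generator has no
nuclear background texture, no segmentation errors, no trace-tracing
errors, no chromatic aberration beyond a uniform channel offset, and its
traces are mutually well separated.  Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to the full failure modes of real microscopy; the quantitative
exclusion rules (effect-size filter, untrackable-trace rule, degenerate
fits) are where those failure modes would surface on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately moderate
sizes — 118 adjacent distances for the gamma fit (the size of the real
persistent-focus data set), 50 nuclei × 40 frames for speed recovery,
200–500 localizations per SMLM fit, 10⁴ samples for goodness-of-fit
checks — chosen so the whole analysis reruns in minutes on one CPU while
keeping estimator noise within the stated tolerances.  At n = 118 the
gamma-shape MLE has a sampling s.d. of ≈ 13% of the true value; the ±20%
recovery criterion reflects that inherent spread, not estimator bias.
All stochastic code paths take a seed or `numpy.random.Generator`;
tie-breaks (equidistant trace assignment → lower trace id), degenerate
inputs (flat profiles, stationary nuclei, empty masks, constant
distances) and clipping rules (folded values to [0, 0.5], intervals to
the trace) are fixed and tested.
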