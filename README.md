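# meiopattern

Quantitative analysis of meiotic crossover patterning dynamics in the
*C. elegans* germline.

During meiosis every chromosome pair must receive at least one crossover
(CO assurance) and additional COs are suppressed nearby (CO interference).
In *C. elegans* the readout of this regulation is a single bright COSA-1
focus per chromosome pair in late pachytene, strongly biased toward the
chromosome arms.  When and how that pattern is established among the much
larger cohort of early recombination intermediates is the question this
package addresses: it implements the full image-analysis and statistics
pipeline needed to (i) order germline nuclei in meiotic pseudotime,
(ii) separate recombination foci into *persistent* and *blinking*
populations along traced synaptonemal complexes (SCs), (iii) quantify arm
bias and interference of each population, and (iv) resolve the
ultrastructure of recombination nodules in 3D single-molecule localization
microscopy (SMLM).

Because the pipeline's inputs are microscopy-derived tables and traces, the
package ships a first-class synthetic-data module that generates every
input with known ground truth, so each stage is testable end to end.

## The statistics at the core

* **Pseudotime staging** — nuclei move through the gonad at a constant rate
  (1.1 h per row of nuclei).  Centroids are PCA-rotated, a LOWESS
  centerline is fitted, and each nucleus's arc-length position is expressed
  relative to late-pachytene onset, located as the inflection point `x₀` of
  a cumulative-Gaussian fit `low + (high−low)·Φ((x−x₀)/w)` to the
  nucleus-level log median focus intensity.
* **Persistent vs blinking classification** — SC traces are resampled at
  120 nm arc-length spacing; each focus detection is assigned to the
  nearest trace and surrounded by an interval of half-width
  `w = √((r_xy cos φ)² + (r_z sin φ)²)` where φ is the local tangent
  elevation; intervals overlapping across frames are merged and a group is
  *persistent* if detected in ≥ 95% of analyzed frames.
* **Arm bias** — positions are folded to the distance to the nearest
  chromosome end (0 = telomere, 0.5 = center); populations are compared by
  Wasserstein distance with BH-adjusted Kolmogorov-Smirnov p-values and a
  Fisher's exact arm/center contingency test at the 0.33 boundary.
* **Interference** — the shape γ of a gamma distribution fitted (ML) to
  adjacent inter-focus distances (γ = 1 ⇔ Poisson, no interference), and a
  normalized interference length in [0, 1] computed from per-chromosome
  focus-count statistics, `L̂ = (mean(N) − var(N)) / mean(N)²`, which is 0
  for Poisson placement and 1 when every chromosome carries exactly one
  focus.
* **SMLM nodule ultrastructure** — localizations are quality-filtered
  (z ∈ ±300 nm, precision ≤ 15/25 nm), clustered with DBSCAN (ε = 100 nm,
  minPts = 20) around the chromosome-axis midline, and each cluster is
  fitted by maximum likelihood with an elliptical model: uniform density
  along a 3D-rotated ellipse perimeter convolved with each localization's
  own anisotropic precision, plus a flat background.  Ring-like fits
  spanning both axis strands mark crossover-designated intermediates.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each takes an optional seed argument):

```bash
python analysis/01_simulate_germline.py 1
python analysis/02_stage_nuclei.py
```

which prints

```
movie: 210 nuclei x 40 frames, 106394 focus detections (1260 persistent / 3773 blinking ground-truth foci)
traces: 36 SCs over 6 nuclei, 144 placed foci -> results/sim
row spacing: 3.79 µm; onset at 71.9 µm along the centerline (direction +1)
transit: 1.08 ± 0.18 h/row across 210 nuclei (configured 1.1 h/row)
5 rows before onset = 5.4 h of meiotic time
```

The staging step recovers the configured 1.1 h/row transit within a few
percent and places late-pachytene onset at the configured intensity-ramp
midpoint; five rows of nuclei therefore correspond to about 5.5 h of
meiotic time.  Continuing with `03`–`07` bleach-corrects intensities
(median frame-40/frame-1 intensity ratio 0.42 raw → 1.00 corrected),
classifies focus groups (persistent ground-truth foci recovered as
persistent groups), measures arm bias of the late-CO preset (90% of folded
positions within 0.33 of a chromosome end), fits the interference gamma
shape, and classifies simulated SMLM doublets/singlets by axis contact
(6/6 doublets → both axes, 4/4 singlets → one axis).

The same functionality is exposed as a thin CLI (`meiopattern simulate`,
`meiopattern stage`, `meiopattern run`, …).

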