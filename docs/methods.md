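# Methods

This note documents the models, algorithms and numerical choices behind
`wormneurite`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Setting

Aging *C. elegans* touch receptor neurons (ALM and PLM) accumulate
morphological abnormalities: novel processes sprouting from the soma (soma
outgrowths) or from the sensory dendrite (neurite outgrowths), focal
enlargements of the process (beads/blebs), sharp bends (kinks) of the
dendrite, and shrinking soma volume.  The package quantifies these features
from two inputs produced upstream: a traced neuron tree in SWC format (one
node per line: id, type, x, y, z, radius, parent) and, for ALM soma volume,
the confocal stack the trace came from.

All thresholds are physical (µm), so SWC coordinates given in voxel units
are converted at read time with per-axis voxel dimensions (defaults
0.223, 0.223, 0.300 µm).  The node radius is scaled by the in-plane (x/y)
factor, since tracing estimates radii in-plane.

## Compartment classification

Nodes are classified into seven categories: `mainbranch`, `soma`,
`somaoutgrowth`, `neuriteoutgrowth`, `pvm`, `vnc_connection`,
`blob_artifact`.

- **Main branch** — the root-to-endpoint path of maximal arclength (sum of
  Euclidean distances between consecutive nodes).  Ties break to the
  smallest endpoint id, making results deterministic.
- **Soma (ALM)** — the connected set of nodes containing the root whose
  radii exceed `soma_radius_threshold`.  The threshold defaults to 2.0 µm:
  dendrite radii run ~0.3–0.8 µm and soma radii ~2.5–4 µm, so the two
  populations separate cleanly; it is configurable because it must be
  re-tunable per dataset.  If the root radius is at or below the threshold
  the classifier raises "no soma found" rather than guessing.
- **Side branches** — every subtree hanging off the backbone is labeled
  homogeneously: attached to a soma node → `somaoutgrowth`; attached to a
  main-branch node → `neuriteoutgrowth`.
- **PVM (PLM only)** — PLM traces often swallow part of the crossing PVM
  neuron.  A side branch containing a node above the soma radius threshold
  (the swept-up PVM soma) marks the crossing; that branch and every side
  branch attaching within ±`pvm_window` (4.0 µm of arclength, configurable;
  the window could equally be read as total width — ±4 µm was chosen) of
  its attachment point are labeled `pvm` and excluded from outgrowth
  counts.  If several side branches carry large-radius nodes, the one with
  the single largest node wins and the rest are logged and fall through to
  `neuriteoutgrowth`.
- **`vnc_connection` / `blob_artifact`** — never inferred.  They are carried
  by reserved SWC structure codes (7 and 8) written by an external tree
  editor, and pass through classification untouched.

The branch inventory records, per side branch, its label, its length
(arclength from the attachment node to the subtree's farthest endpoint) and
its attachment position along the main branch measured from the root end.
Soma outgrowths attach inside the soma blob at the root end and report
attachment 0.0.

## Sharp bends (kinks)

For every main-branch node, the nodes within `bend_window` (2.0 µm) of
*accumulated arclength* on each side are fitted with one line per side.
The fit is the total-least-squares principal direction (leading right
singular vector of the centered neighbor coordinates), so it is invariant
under rotation of the coordinate frame — an ordinary regression of y on x
would not be.  Both directions are oriented away from the node, and the
node's turning angle is the angle they subtend, computed as
`atan2(‖u×v‖, u·v)`.  This two-argument form is numerically stable near 0°
and 180°, where the pure arcsine of the cross-product magnitude is
ambiguous.  A straight run gives 180°; a sharp kink gives a small angle.
Nodes within one window of either end of the branch get no angle: a
one-sided fit biases the estimate.

Nodes with angles below `bend_threshold` (155°) are candidates.  To count
each physical kink once, candidates are selected sequentially from the
sharpest; after each selection, all candidates within `bend_nms` (4.0 µm of
arclength) are suppressed (non-maximum suppression).  The implementation
marks suppressed candidates in one pass; a test verifies it equals the
exhaustive greedy selection recomputed from scratch at every step.  Bend
density is the count divided by the main-branch length, and a threshold
sweep (135°–165°) reports density as a function of the threshold; since
loosening the threshold only adds weaker candidates, the density is
non-decreasing in the threshold.

An alternative bend measure — the curvature profile of a smoothing cubic
B-spline through the main branch, parameterized by arclength — is exposed
as a diagnostic (`spline_curvature`) but never used for counts: windowed
line fits are markedly more robust to tracing noise.

## Beads and blebs

Focal enlargements are detected from the traced radii alone.  The local
thickness at a node is the mean radius over nodes within ±4 µm of arclength
(an 8 µm window); subtracting it from the node radius leaves a residual
that is insensitive to slow thickness trends (a linear taper cancels
exactly in the window interior).  Residual maxima are selected
sequentially, with the same 4 µm suppression, while they exceed
`bead_sd_multiplier` (2.0) × the standard deviation of the residuals over
the whole branch.  The SD is taken over residuals rather than raw radii
(raw radii mix the trend back in); the raw-SD variant is available via
config.  Bead density is count over length.

## Soma volume

The ALM soma is segmented by seeded confidence-connected region growing:
starting from the cubic neighborhood (radius `init_radius` = 1 voxel) of
the seed — the soma node nearest the tree root, mapped to voxel
coordinates — the region's intensity mean µ and SD σ are computed, a
26-connected flood fill from the seed accepts voxels in
[µ − `multiplier`·σ, µ + `multiplier`·σ], and the statistics/flood cycle
repeats `iterations` times (defaults: multiplier 2.5, 4 iterations — the
common defaults of this algorithm family).  A region flooding more than
half the stack raises a "segmentation overflow" error, the signature of a
bad seed or an over-wide band.

Two protocol points matter for accuracy:

- **Segment the raw stack.**  Gaussian pre-smoothing (sigma 0.7, 0.7, 0.52
  voxels) exists to help tracing.  Smoothing before region growing
  collapses the voxel-noise statistics that the confidence band is built
  from; with a near-zero σ the band hugs the bright interior and carves
  the soma at the top of its edge ramp, biasing volumes low by tens of
  percent.  On the unsmoothed stack the photon noise sets a band that
  lands near the half-maximum edge, where a blurred sphere's boundary
  belongs.
- **Close before opening.**  The raw flood mask has a noise-rough crust;
  opening it directly erodes a roughly one-voxel shell.  The cleanup is
  therefore closing + hole filling + opening (ball of `opening_radius` = 1
  voxel in index space; anisotropy ignored for this cleanup step), after
  which the component containing the seed is kept.  The opening still
  serves its purpose of stripping the thin dendrite stub.

Volume is the voxel count times dx·dy·dz.  On rendered test spheres
(r = 1.5–3.5 µm, PSF blur + Poisson noise at ~50 photons per unit
intensity, 20 seeds) the recovered volume is within a few percent of the
analytic value with no systematic bias; a noiseless digital sphere is
recovered within digitization error (<3%).

For PLM tracing, `find_boundary_seed` returns the brightest voxel on the
six faces of the stack — where the dendrite crosses the field-of-view
boundary — with ties broken by index order, and writes it as a 1-based
Vaa3D `.marker` seed.

## Spatial statistics

The dendrite is treated as a 1D segment; bends and outgrowth attachment
points are located by arclength distance from the most distal main-branch
point.  All distances are along the stretched neuron, not 3D chords.

- **Empty-space function.**  For the bend pattern {b₁…b_k} on [0, L],
  F(r) is the fraction of the segment within r of some bend, computed
  exactly from the union of the clipped intervals [bᵢ−r, bᵢ+r] — no
  sampling.  If outgrowths fall uniformly and independently of bends, the
  probability that an outgrowth lies within r of a bend is exactly F(r).
- **Association test.**  Per neuron with at least one bend and one
  outgrowth, the observed fraction of outgrowths within the interaction
  distance r (default 1 µm) is paired with F(r); a Wilcoxon signed-rank
  test (exact distribution up to 25 pairs, zeros dropped, one-sided
  "greater" by default since the claim is directional; two-sided by flag)
  evaluates the paired differences across the cohort.  Neurons lacking
  bends or outgrowths are excluded (and counted in the log); below 6
  usable pairs the test is near-vacuous and a warning is issued.  Pooled
  curves (cohort-mean nearest-distance CDF and cohort-mean F) are returned
  on a 0–10 µm grid (0.1 µm step) for plotting.
- **Group comparisons.**  Two-sample Kolmogorov–Smirnov on pooled event
  positions (exact p for ≤25 observations per sample, asymptotic above)
  and percentile-bootstrap 95% CIs of group means (10,000 resamples by
  default, deterministic under a seed).

### A calibration caveat

The signed-rank test assumes the paired differences are symmetric under
the null.  With m outgrowths on a neuron, the observed fraction is
Binomial(m, F(r))/m; its difference from F(r) has mean zero but is skewed
whenever m·F(r) is small — with realistic values (m ≈ 3, F(1 µm) ≈ 0.08)
the difference is negative with probability ≈ 0.8.  The consequence,
verified by simulation (2000 cohorts), is that the test is **conservative**
at realistic event densities: the type-I error at α = 0.05 is ≈ 0.003, and
it climbs toward the nominal level only as per-neuron outgrowth counts
grow (≈ 0.03 at 30–65 outgrowths/neuron, ≈ 0.04 at 150).  It never
over-rejects.  For the directional claim the method is used for, this
means reported significances err on the safe side; it also means the test
has less power than a calibrated test would at the same α.  Power is
nonetheless high for the planted effect size of interest: with 80% of
outgrowths placed within 0.5 µm of a bend in 19-neuron cohorts, the
rejection rate at α = 0.05 is ≈ 1.0 (500 cohorts).

## Synthetic data

The generator plants known structure so every stage is testable without
microscope data:

- A main dendrite of chosen length with corner nodes placed exactly at the
  planted bend arclengths; the turn direction out of the local plane is
  randomized so tests exercise genuine 3D geometry.
- Side branches (chains) with planted labels, lengths and attachment
  arclengths; a PVM-like branch carries one soma-sized (3 µm radius) node;
  an optional soma is a large-radius root with an inscribed shell of
  large-radius nodes, so its rendered union of node spheres is exactly the
  soma sphere.
- Radii are baseline (0.4 µm) plus Gaussian bead bumps plus optional white
  noise, floored at 0.05 µm.
- Coordinate noise is **smooth**: white per-node displacements are
  low-pass filtered along each chain (~1 µm correlation length) and
  rescaled to the requested SD.  White jitter at 0.2 µm node spacing would
  inflate every measured arclength by ~13% (each step gains
  √(Δs² + 2σ²) − Δs), an artifact real traces do not show, and would
  decouple planted from measured event positions.
- Rendering stamps spheres along nodes and edges (unit intensity) over a
  uniform background (default 0.1 — autofluorescence plus detector
  offset; a zero background would make the confidence band unbounded
  below once edge voxels enter the region statistics), blurs with an
  anisotropic Gaussian PSF (0.7, 0.7, 0.52 voxels) and applies Poisson
  photon noise at a configurable expected count.  Everything is
  deterministic under the spec's seed.

Cohort generation emulates an aged wild-type PLM population at the
distribution level: 300 µm dendrites; bend counts Poisson at density
0.04 µm⁻¹ (~12 bends/neuron, in the range of per-neuron counts the
detector is designed for) with a 6.5 µm minimum separation; bend angles
uniform in 90°–150°; outgrowth counts Poisson with mean 3; outgrowth
lengths log-normal (median ≈ 4 µm); 19 neurons per cohort.  A coupling
knob places each outgrowth within a fixed distance of a random bend with
probability p — the generative signal the association test must detect;
p = 0 is the independence null.

What passing tests show — and what they do not: the generator produces
clean single trees with chain-shaped side branches, smooth noise and
isolated somas.  It does not emulate stitching artifacts, gaps or
re-traced segments, crossing processes from other neurons (beyond the one
PVM-like branch), irregular soma shapes, or depth-dependent attenuation.
Recovery results on synthetic data therefore validate the algorithms and
their implementations, not performance on any particular real dataset;
thresholds (soma radius, bend angle, SD multiplier) are exposed in config
precisely because real data needs per-dataset checks.

## Problem sizes and determinism

The recovery studies use 100 branches (0–10 planted bends each), 100
classification trees, 20 rendered spheres, 10 bead seeds, and 2000/500
simulated cohorts for calibration/power — sizes at which the binomial
uncertainty of the measured rates is well inside the asserted margins.
Every random stage takes an explicit seed; the batch pipeline records a
hash of its full config in every output row, and re-running with the same
seed reproduces the CSV/JSON outputs byte for byte.
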