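# Methods

`ductcpr` implements an automated pipeline for curved planar
reconstruction (CPR) images along the main pancreatic duct (MPD):
pancreas and duct segmentation, centerline detection by shortest-path
routing, CPR resampling, MPD length measurement, and the ordinal
agreement statistics used to evaluate such pipelines.  Because clinical
CT and human raters are out of reach for an open test suite, every
stage is validated against a synthetic CT phantom generator with exact
ground truth.

## Phantom model

A phantom is a tube (the duct) inside a thicker tube (the parenchyma)
on a dark background, mimicking pancreatic-phase contrast CT where the
fluid-filled duct is hypodense against enhancing parenchyma.

* **Curve model.** A cubic spline through ≥4 control points,
  chord-length parameterized and resampled at 0.25 mm arc-length steps.
  The dense sample is the ground-truth centerline; the analytic length
  is integrated by chord summation at 0.02 mm steps (chord-vs-arc error
  far below the 0.1 % documentation tolerance).
* **Rasterization.** A voxel belongs to the lumen when its center lies
  within the local duct radius of the curve (distance via a k-d tree
  over the dense sample); the lumen is cut flush at the curve ends so
  its extent equals the curve's arc span.  The parenchyma extends a
  configurable margin radially but at most `end_cap_mm` (default 2 mm)
  longitudinally past the duct ends — the gland barely outlives the
  duct, which fixes the head-to-tail convention (head at max world-x).
* **Tumor gaps.** Arc-length intervals where the lumen reverts to
  parenchyma intensity, splitting the duct into segments.  Gaps must be
  disjoint and strictly interior to the curve.
* **Intensities and noise.** Defaults: parenchyma 100 HU, duct 20 HU,
  background −50 HU (plausible pancreatic-phase placeholders; all
  configurable), plus seeded i.i.d. Gaussian noise (default SD 10 HU,
  near the scanners' targeted noise level).  Truth masks are noise-free.
  Identical (spec, seed) yields bit-identical output.
* **Cohorts.** `preset_study_cohort` draws duct diameters as
  3 + 10·Beta(2, 7) mm clipped to [3, 13] (sample median ≈ 5 mm) with
  duct lengths 90–130 mm, matching the dilated-duct population the
  pipeline targets; `preset_stress_cohort` draws 1.5–2 mm non-dilated
  ducts for the failure mode; `preset_mini_cohort` makes 32³ phantoms
  at 1.5 mm spacing with 5.2–9 mm ducts (≥3 voxels wide, the minimum a
  tube needs to survive the morphological post-filter) for CNN
  training.  Voxel grids are 0.5 mm in-plane with 1 mm slices for the
  study-scale cohorts — the coarse end of high-resolution abdominal CT,
  chosen so the full multi-phantom suite runs in minutes on one CPU.

What the phantoms deliberately lack: organ texture, contrast-phase
dynamics, reconstruction-kernel noise spectra, anatomy other than a
single duct.  Passing tests therefore demonstrate geometric and
algorithmic correctness, not clinical segmentation performance.

## Segmentation

Two interchangeable backends return pancreas and duct masks with
`duct ⊆ pancreas` enforced.

* **Classical (reference surface).** The pancreas is the largest
  connected component above a threshold midway between background and
  duct intensity (default −15 HU) after binary closing; the duct is
  every voxel below `duct_threshold_hu` (default 60 HU, midway between
  duct and parenchyma) inside the pancreas.  The post-filter is
  *opening-by-reconstruction* — a 1-voxel 6-connected erosion followed
  by `binary_propagation` inside the raw mask — plus removal of
  components smaller than 20 voxels.  Reconstruction is used instead of
  plain opening because it removes speckle and sub-3-voxel tubes
  identically while leaving the surviving duct's end and gap faces
  unbiased; plain opening erodes each face by ~1 voxel and that bias is
  visible in measured MPD lengths.  Thin (≤2 mm) ducts at 1 mm slice
  spacing do not survive the erosion seed — reproducing the clinically
  observed undetectability of non-dilated ducts.
* **Mini 3D U-Net.** A numpy implementation (im2col convolutions,
  hand-derived backpropagation verified against finite differences,
  Adam): two resolution levels, 8 base channels, two independent
  sigmoid heads (pancreas, duct), soft-Dice loss, 32³ patches, default
  20 epochs at learning rate 3·10⁻³.  The head convolution is
  zero-initialized, so an untrained network predicts exactly 0.5 and
  the strict >0.5 threshold yields empty masks — the downstream
  fallback rule then still produces a centerline.  Inference tiles
  arbitrary volumes with overlap-averaged 32³ patches and applies the
  same post-filter as the classical backend.  This network is a
  deliberately desk-scale demonstration of the CNN pathway, orders of
  magnitude smaller than clinical models.

## Centerline detection

The centerline rule has two cases: (a) where a segmented duct exists
the path runs through the duct; (b) where it does not, the path runs
approximately through the center of the pancreas.  Both are encoded in
one cost field and one Dijkstra search.

* **Endpoints.** Two breadth-first sweeps (26-connectivity) find the
  geodesically farthest voxel pair of the pancreas mask — exact on
  tubular shapes; ties break lexicographically.  The head is the
  endpoint with larger world-x (configurable axis/sign).  When a duct
  mask exists, each endpoint snaps to the nearest duct voxel within
  `endpoint_snap_mm` (default 10 mm): the gland's geodesic extremes lie
  on its outer surface, while the duct terminus is the anatomically
  correct start of the MPD course.
* **Cost field.** `cost = scale / (1 + d_boundary)` with `d_boundary`
  the anisotropy-aware Euclidean distance to the region boundary:
  scale ε = 0.01 inside the duct, 1 inside the pancreas, and a finite
  barrier 10⁶ outside.  Medial voxels are cheapest within each region
  and every duct voxel is cheaper than every pancreas voxel at organ
  scale, so the route prefers the duct core (case a) and falls back to
  the pancreas medial axis where the duct is absent (case b).  The
  medialness factor inside the duct matters: a constant lumen cost
  would let the shortest path cut corners across wide (≥10 mm) ducts.
* **Dijkstra.** 26-connected voxel graph; edge weight
  `(cost(u)+cost(v))/2 ×` Euclidean step (mm).  The priority queue is
  keyed on (distance, flat voxel index) and predecessors update only on
  strict improvement, so results are bit-reproducible; the search is
  verified against an independent Bellman–Ford relaxation on random
  instances.
* **Refinement.** The voxel path is smoothed by a 9-point moving
  average whose padding mirrors *through* the endpoints (a straight end
  is a fixed point, so smoothing cannot retract the path), recentered
  by a small-ball mean-shift toward the local lumen centroid with the
  longitudinal component removed (centers the path laterally without
  pulling it off the duct end faces), smoothed once more to remove
  centroid jitter, and resampled at uniform 0.5 mm arc steps.
* **Labels and segments.** Each point is labeled duct/fallback by duct
  mask membership; an interior fallback run longer than
  `gap_tolerance_mm` (default 5 mm) marks a segment break — a
  tumor-interrupted duct.

## CPR and length

* **Frames.** Tangents by central differences; normals transported by
  the double-reflection rotation-minimizing scheme (orthonormal to
  10⁻⁹), initial normal defaulting to the world axis least aligned with
  the first tangent (caller-overridable).
* **Resampling.** Rows step along arc length, columns laterally over
  ±`lateral_halfwidth_mm` (default 20 mm at 0.5 mm steps); intensities
  are trilinear; out-of-volume samples take −1000 HU (air).
  `straightened` mode sweeps the rotation-minimizing normal;
  `projected` mode sweeps a fixed direction orthogonalized against the
  tangent and reduces exactly to a planar reformation for a straight
  path — the limit case used as an oracle.  The center column
  reproduces the centerline samples to 10⁻⁶ mm.
* **Length.** Per-segment polyline lengths between segment breaks, with
  leading/trailing fallback points trimmed; the total is the sum of the
  segments (the rule for tumor-divided ducts).  A pure-fallback path
  counts as one whole segment.  Chord sums underestimate arc length and
  converge monotonically as the resampling step shrinks.

## Statistics

* **Weighted κ.** `κ = 1 − Σw·p_obs / Σw·p_exp` with distance weights
  `|i−j|/(k−1)` (linear, default — the weight scheme an ordinal
  four-point scale most commonly uses) or squared (quadratic); expected
  disagreement from marginal products.  95 % CIs by case-resampling
  bootstrap (2000 replicates, percentile, seeded).  Bands: poor
  (0.0 ≤ κ ≤ 0.2), fair (0.2 < κ ≤ 0.4), moderate (0.4 < κ ≤ 0.6),
  good (0.6 < κ ≤ 0.8), excellent (0.8 < κ ≤ 1.0); κ < 0 reports
  "poor" with a below-chance flag on the result object.  The 95 % CI is
  a case-resampling bootstrap (2000 replicates, seeded) with the BCa
  (bias-corrected and accelerated) correction: in calibration
  simulations at n = 100 the plain percentile interval covered a true
  κ = 0.75 only ~92 % of the time, the basic interval ~90 %, and BCa
  ~94 % — closest to nominal.  The acceleration constant comes from a
  leave-one-case-out jackknife evaluated per distinct contingency cell.
* **Simulation model.** Rating pairs with target agreement are drawn
  from the mixture `p_ij = κ·δ_ij·m_i + (1−κ)·m_i·m_j`, whose weighted
  κ equals the mixing weight exactly for any distance-based weight
  scheme — convenient for null (κ = 0) and coverage simulations.
* **Sample size.** The smallest n in a grid for which the *median*
  lower 95 % CI bound over ≥500 simulated cohorts exceeds the target
  threshold (e.g. 0.6) — an operationalization of sizing a study so the
  κ CI lower limit clears a required agreement level.
* **Paired t-test.** Two-sided on per-case differences (df = n−1) via
  `scipy.stats.ttest_rel`, with explicit degenerate-input errors for
  zero-variance differences.

## Numerical and degenerate-input choices

* World convention: `world = origin + index · spacing`, axis-aligned
  affines only; rotated NIfTI headers are rejected explicitly.
* Dijkstra/BFS ties break lexicographically on flat voxel index.
* Disconnected pancreas masks fall back to the largest component with a
  warning; single-voxel masks raise degenerate-path errors.
* Empty duct masks are legal everywhere (they select the fallback
  rule); empty pancreas masks are errors.
* Two empty masks have Dice 1.0 by definition.
* All randomness flows through `numpy.random.default_rng` seeds carried
  in specs/configs; pipeline reruns are byte-identical.

## Problem sizes used in the shipped checks

Phantom cohorts of 20 (noise-free, 3–13 mm), 6 (fallback), 5 + 5
(noisy failure-mode), U-Net training on 16 phantoms for 20 epochs with
4 held out, 100 random 5³ cost fields for the routing oracle, 1000
independence cohorts, 250 coverage cohorts at n = 100 with 2000
bootstrap replicates, and 10 000 null paired t-tests.  These sizes keep
a full run in the tens of minutes on a single CPU while leaving the
statistical margins comfortably wider than the assertion bands.

## Known limitations

* Phantoms are geometric idealizations; real pancreata have irregular
  parenchyma, neighboring organs of similar intensity, and partial
  volume effects the binary rasterization does not model.
* The classical backend's thresholds assume the phantom intensity
  model; on real CT they would need calibration.
* The mini U-Net demonstrates the CNN pathway, not clinical accuracy.
* Branch ducts, stents, and multi-path CPR are out of scope.
* The reported κ values of clinical reader studies cannot be reproduced
  here; the statistics module is validated on its mathematical
  properties (exact oracles, null behavior, CI coverage) instead.
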