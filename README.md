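# ductcpr

Automated **curved planar reconstruction (CPR) along the main pancreatic
duct (MPD)**, with the synthetic phantoms and evaluation statistics
needed to validate every stage.

Abrupt caliber change or interruption of the MPD is a key CT sign of
pancreatic cancer, and a CPR image displays the duct's whole winding
course in a single 2D picture — but producing one by hand means placing
many cursors along the duct on axial slices.  `ductcpr` implements the
automated alternative as a reusable library and CLI:

1. **Segmentation** of pancreas and duct from a contrast-CT-like volume
   (a deterministic classical backend, plus a miniature 3D U-Net
   trained on phantoms);
2. **Centerline detection** from pancreatic head to tail with
   Dijkstra's algorithm on a voxel cost graph.  The centerline either
   (a) passes through the segmented duct, or (b) falls back to running
   approximately through the center of the segmented pancreas where the
   duct is undetectable — the two-case rule that keeps the pipeline
   working on non-dilated ducts;
3. **CPR resampling** (straightened or projected sweep, rotation-
   minimizing frames) and **MPD length measurement**, where a duct
   divided by tumor is measured as the sum of its segments;
4. **Statistics** for evaluating such pipelines on ordinal quality
   scores: weighted Cohen's κ with bootstrap CIs and the conventional
   poor/fair/moderate/good/excellent bands, paired t-tests, and a
   κ-CI-driven sample-size search.

Because clinical CT cannot ship with a test suite, the package includes
a seeded **phantom generator**: CT-like volumes of a hypodense duct in
enhancing parenchyma with exact ground-truth masks, centerline, and
analytic arc length, covering the dilated range (3–13 mm diameters,
median ≈ 5 mm) and a non-dilated 1.5–2 mm stress range.

## The core computation

The centerline is the minimum-cost 26-connected voxel path between the
geodesically farthest pair of pancreas voxels (head at larger world-x),
with edge weight `(cost(u)+cost(v))/2 · ‖step‖mm` and

```
cost(v) = ε / (1 + d_duct(v))      inside the duct      (ε = 0.01)
        = 1 / (1 + d_panc(v))      inside the pancreas
        = B                        outside              (B = 10⁶)
```

where `d_·` is the distance to the region boundary in mm — so the route
hugs the duct's medial core where a duct exists and the pancreas medial
axis where it does not.  The path is smoothed, recentered in the lumen,
resampled at 0.5 mm, and labeled per point as `duct` or `fallback`;
fallback runs longer than 5 mm split the duct into segments.

Agreement between two raters or methods scoring cases 1–4 is

```
κ_w = 1 − Σ w_ij p_ij / Σ w_ij e_ij ,   w_ij = |i−j|/(k−1)
```

with `e_ij` from the marginal products and a case-resampling,
bias-corrected (BCa) bootstrap 95 % CI.

## Worked example

```python
import numpy as np
from ductcpr import (preset_study_cohort, generate_phantom, segment_classical,
                     extract_centerline, generate_cpr, measure_mpd_length,
                     dice, RatingTable, weighted_kappa)

# a 5.2 mm duct with one tumor gap, 10 HU noise, known ground truth
spec = preset_study_cohort(1, seed=7, noise_sd_hu=10.0, gap_fraction=1.0)[0]
vol, truth = generate_phantom(spec)

seg  = segment_classical(vol)
path = extract_centerline(seg.pancreas_mask, seg.duct_mask)
m    = measure_mpd_length(path)
cpr  = generate_cpr(vol, path)

print("duct Dice vs truth:", round(dice(seg.duct_mask, truth.duct_mask), 3))
print("measured length:", round(m.total_mm, 1), "segments:",
      [round(x, 1) for x in m.per_segment_mm])
print("truth length:", round(truth.analytic_length_mm, 1))
print("CPR image:", cpr.pixels.shape)
```

prints

```
duct Dice vs truth: 1.0
measured length: 117.8 segments: [68.4, 49.4]
truth length: 118.3
CPR image: (256, 81)
```

— the duct is segmented essentially perfectly at this noise level, the
tumor gap splits the course into two segments whose sum (117.8 mm) is
within 0.5 % of the phantom's analytic 118.3 mm, and the CPR image has
one row per 0.5 mm of arc length with the duct running down its center
column.  Rating tables work the same way:

```python
rng = np.random.default_rng(0)
a = rng.choice([2, 3, 4], size=100, p=[0.02, 0.22, 0.76])
b = np.where(rng.random(100) < 0.8, a,
             rng.choice([2, 3, 4], size=100, p=[0.02, 0.22, 0.76]))
r = weighted_kappa(RatingTable.from_scores(a, b), seed=0)
print(f"kappa {r.kappa:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}) band={r.band}")
# kappa 0.777 (95% CI 0.616-0.901) band=good
```

The same stages are available from the shell:

```bash
ductcpr phantom --seed 7 --out ph/
ductcpr pipeline --volume ph/volume.nii.gz --out run/   # masks, centerline, CPR, length
ductcpr stats kappa --ratings ratings.csv
```

## Layout

```
src/ductcpr/
  phantom.py       seeded CT phantom generator + ground truth
  segmentation.py  classical backend, Dice
  unet.py          miniature numpy 3D U-Net backend
  centerline.py    endpoints, cost field, Dijkstra, extraction
  cpr.py           frames, CPR resampling, length measurement
  stats.py         weighted kappa, bands, t-tests, sample size
  io.py            NIfTI/JSON/PNG I/O
  pipeline.py      config + end-to-end runner
  cli.py           `ductcpr` command line
docs/methods.md    model, parameters, numerical choices, limitations
```
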