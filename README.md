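# cuticlevol

Unsupervised measurement of exoskeleton (cuticle) and whole-body volumes from
x-ray microtomography slice stacks, with standardized major axis (SMA)
allometry for comparing cuticular investment across species and castes.

## What it does

A microtomography scan of an insect arrives as a stack of grayscale slice
images. In each slice, cuticle appears as bright closed bands and the
enclosed soft tissue as a darker filling. `cuticlevol` turns such a stack
into two numbers per specimen — cuticle volume and total body volume — with
no training data and no manual tracing:

1. **Per-slice segmentation** (`segment_slice`). Each slice is contrast
   stretched and bilateral-filtered, the scanning-vial rim (if present) is
   detected and cropped away, and an intensity band capturing cuticle is
   thresholded. The lower band edge can be resolved automatically by 1-D
   k-means on sampled slices (tissue vs. cuticle class means). Contours are
   extracted with their containment hierarchy: pixels inside an outermost
   contour count toward the body; pixels between a cuticle contour and the
   holes it encloses count toward the cuticle. Speckle below a perimeter
   cutoff is discarded; nearly closed "orphan" cross-sections are closed by
   convex hull, and open contour arcs are linked by endpoint proximity.
2. **Series repair** (`rolling_median_correct`). Counts vary smoothly from
   slice to slice, so punctual segmentation failures (a contour that fails to
   close on one or two slices) show up as isolated spikes in the per-slice
   count series. A rolling-median (Hampel) detector flags them and replaces
   flagged runs by linear interpolation from the nearest clean slices,
   leaving every clean slice untouched. A plain centered rolling median is
   available as `mode="median"`.
3. **Integration and stitching** (`integrate_volumes`, `merge_series`). Pixel
   counts are summed and scaled by the voxel volume (pixel size cubed).
   Specimens taller than the field of view are scanned in overlapping height
   steps; `find_overlap` aligns consecutive count series on their overlap and
   `merge_series` fuses them into one profile.
4. **Allometry** (`sma_fit`, `test_slope_equals`, `test_common_slope`). SMA
   regression of log cuticle volume on log body volume quantifies relative
   cuticular investment; hypothesis tests compare fitted slopes against
   isometry and across castes.

Everything is validated against **synthetic phantoms** (`make_hollow_shell_stack`,
`make_ant_like_stack`): rendered hollow shells whose per-slice pixel counts
are known exactly by construction, optionally embedded in a bright vial,
degraded with Gaussian noise and blur, split into height steps, or corrupted
with count spikes.

## Worked example

End-to-end run on a synthetic specimen with known ground truth. This is the
exact script that produced the output below:

```python
import cuticlevol as cv

# 1. Make a synthetic specimen with known ground truth: a hollow sphere
#    (radius 20 px, shell 3 px) in a 48x96x96 stack at 2.44 um/px.
spec = cv.PhantomSpec()
stack, truth = cv.make_hollow_shell_stack(spec)

# 2. Put it in a bright scanning vial and add realistic noise and blur.
stack = cv.embed_in_vial(stack, vial_radius=44, rim_intensity=55000)
stack = cv.degrade(stack, seed=1)

# 3. Segment every slice, repair punctual failures, integrate volumes.
series = cv.segment_stack(stack, cv.SegConfig(), pixel_size_um=2.44)
series = cv.rolling_median_correct(series, window=5)
volumes = cv.integrate_volumes(series, cv.ScanMeta("demo", pixel_size_um=2.44))

print(f"cuticle volume: {volumes.cuticle_volume_um3:,.1f} um^3")
print(f"body volume:    {volumes.body_volume_um3:,.1f} um^3")
print(f"cuticle/body:   {volumes.ratio:.4f}")

true_cut = truth.total_cuticle * 2.44**3
true_body = truth.total_body * 2.44**3
print(f"error vs truth: cuticle {abs(volumes.cuticle_volume_um3-true_cut)/true_cut:.2%}, "
      f"body {abs(volumes.body_volume_um3-true_body)/true_body:.2%}")
```

Output:

```
cuticle volume: 184,984.1 um^3
body volume:    483,458.6 um^3
cuticle/body:   0.3826
error vs truth: cuticle 1.13%, body 0.81%
```

On the same phantom without noise, the recovered per-slice counts are
bit-identical to the rendered truth (see the acceptance results below).

### Allometry example

Given a per-scan table with columns `species`, `caste`, `cuticle_volume_um3`
and `body_volume_um3`, compute species means and fit caste-level SMA slopes
on log10 scales. On a simulated 30-species table with a true worker exponent
of 0.97 this prints:

```python
means = cv.species_means(df)
res_w, fit_w = cv.standardized_investment(means, "worker")
res_q, fit_q = cv.standardized_investment(means, "queen")
iso = cv.test_slope_equals(fit_w, 1.0)
common = cv.test_common_slope([fit_w, fit_q])
r2, slope, p, n = cv.caste_correlation(res_w, res_q)
print(f"worker SMA slope = {fit_w.slope:.3f} [{fit_w.ci[0]:.3f}, {fit_w.ci[1]:.3f}], "
      f"r2 = {fit_w.r2:.3f}, n = {fit_w.n}")
print(f"isometry test: t = {iso.statistic:.2f}, P = {iso.p_value:.3f}")
print(f"worker vs queen common slope: P = {common.p_value:.3f}")
print(f"caste investment correlation: r2 = {r2:.2f}, slope = {slope:.2f}, n = {n}")
```

```
worker SMA slope = 0.969 [0.940, 0.999], r2 = 0.994, n = 30
isometry test: t = -2.09, P = 0.046
worker vs queen common slope: P = 0.732
caste investment correlation: r2 = 0.01, slope = -0.98, n = 30
```

## Command line

The `cuticlevol` command exposes the pipeline for folders of TIFF/PNG slices:

```bash
# Generate a synthetic scan with ground truth
cuticlevol phantom --out scan/ --kind hollow_sphere --seed 1

# Segment it (magnification 2/5/10 maps to pixel sizes 6.11/2.44/1.22 um)
cuticlevol segment scan/ --pixel-size-um 2.44 --out results/demo

# Merge overlapping height steps
cuticlevol stitch step1/counts.csv step2/counts.csv --out merged.csv

# SMA allometry on a per-scan volume table
cuticlevol allometry volumes.csv --caste worker --out results/allometry

# Correlate automated volumes against a reference table
cuticlevol validate results/demo/volumes.csv reference.csv
```

`segment` writes a per-slice count CSV, integrated volumes, optional color
overlay images (cuticle orange, interior blue) and a run manifest. Every
stochastic step derives from `--seed`, and `--config` accepts a YAML file
mirroring `SegConfig` and run options.

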