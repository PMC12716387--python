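# Methods

This document records the model behind each pipeline stage, the default
parameters and why they have their values, the construction of the synthetic
phantoms used for validation, and the known limitations. All claims about
accuracy below are the ones computed by `tests/` and
`scripts/acceptance.py`; nothing here asserts performance that the shipped
code does not measure.

## 1. Slice model

A microtomography slice of an insect in an ethanol-filled vial contains up
to four intensity classes, ordered by x-ray density: mounting medium
(background), soft internal tissue, cuticle, and — if the field of view
includes it — the vial wall, which is far brighter than any tissue. The
cuticle is the animal's outermost dense layer, so on a slice it forms
closed bands: the external boundary of each body cross-section, possibly
with internal dense structures nested deeper inside.

The segmentation exploits exactly this geometry. It never learns from data;
every decision is a deterministic rule on intensity and contour nesting.

## 2. Per-slice segmentation (`slice_seg`)

The decision tree, in order:

1. **Enhancement** (`enhance_slice`). Linear contrast stretch of the slice
   (or of a caller-supplied `stretch_range`, see §3) to [0, 1], followed by
   an edge-preserving bilateral filter (`bilateral_sigma_spatial = 3` px,
   range sigma = `0.1` of the stretched range). The bilateral filter
   suppresses grain noise without blurring the tissue/cuticle boundary the
   threshold depends on.
2. **Vial removal** (`detect_and_crop_vial`). The vial rim is found as a
   bright (above-Otsu) connected component that (a) fills at least
   `vial_min_area_frac = 0.6` of the frame once its holes are filled,
   (b) has its centroid in the central quarter of the frame, and (c) is
   ring-like (filled area at least twice the wall area — a solid blob
   fails this). Everything on or outside the rim, plus a
   `vial_rim_margin = 3` px safety erosion inside it, is replaced by the
   background level (the modal gray value). Absence of a vial is not an
   error; the slice passes through unchanged.
3. **Band threshold** (`threshold_band`). Pixels with intensity in
   `[t_lo, t_hi]` are foreground. `t_hi` defaults to the bit maximum;
   `t_lo`, if not given, is resolved by deterministic 1-D k-means
   (`band_lower_threshold`): three means initialized at min / midrange /
   max locate the medium, tissue and cuticle classes, and the threshold is
   the midpoint of the tissue and cuticle class means — the decision
   boundary that keeps only the densest class. If the middle class holds
   under 1 % of pixels the histogram is treated as two-class and the
   midpoint of those two means is used. Lloyd's algorithm on sorted 1-D
   data with fixed initialization has no random component, so the threshold
   is reproducible bit-for-bit.
4. **Contour hierarchy** (`extract_contour_tree`). External contours are
   connected foreground components; the holes of each are the connected
   components of its filled interior minus the component itself. Working
   mask-wise (rather than with polygonal contours) makes pixel counts exact
   and depth/solidity rules unambiguous.
5. **Hierarchy filtering** (`filter_hierarchy`). Only top-level external
   contours and their direct holes are kept. Deeper-nested externals
   (dense structures inside the body) are dropped: their pixels fall inside
   a kept hole and therefore count as body, not cuticle. Contours with
   perimeter strictly below `min_perimeter = 40` px are removed — small
   externals are speckle; a small hole is absorbed into the cuticle. The
   filter is idempotent (property-tested on random masks).
6. **Closure of open cross-sections** (`close_orphans`,
   `link_open_contours`). Some body regions are genuinely open rings on a
   slice (e.g. the unfused segments of a gaster). They threshold to
   childless external contours with low solidity
   (`orphan_solidity_cutoff = 0.9`). Where several such arcs have endpoint
   gaps of at most `linking_max_gap = 10` px, minimal bridging segments are
   drawn and the hierarchy re-extracted; a region still open afterwards
   falls back to convex-hull closure and is flagged. Compact blobs and
   closed annuli are untouched.
7. **Counting** (`segment_slice`). Cuticle pixels = kept external regions
   minus kept hole interiors (boundary pixels count as cuticle). Body
   pixels = external regions with holes filled. A slice with no surviving
   contour yields (0, 0) — correct for background-only slices above and
   below the specimen.

## 3. Stack processing (`stack_proc`)

`segment_stack` fixes two quantities once per stack so all slices share one
gray mapping:

* **Stretch range.** The contrast stretch uses the stack-wide intensity
  range, not per-slice ranges, so that `t_lo` means the same gray level on
  every slice. When vial detection is on, the range is computed from nine
  evenly spaced sample slices *after* vial cropping: a 55 000-level rim in a
  16-bit image would otherwise compress the specimen's 5 000–30 000 range
  into a fraction of the stretched scale and bias the k-means threshold.
  With this choice, embedding a phantom in a vial changes its recovered
  per-slice counts by exactly zero (acceptance key
  `vial_volume_rel_change = 0`).
* **Threshold.** `t_lo` is resolved once on the pooled sample slices and
  passed to every slice as an explicit config value.

### Rolling-median repair (`rolling_median_correct`)

Cross-sectional areas of a connected 3-D body vary continuously along the
stack axis, so the per-slice count series is smooth at the slice scale.
Punctual segmentation failures — a contour that fails to close on one or
two slices, so a hole's interior is misattributed — produce isolated spikes
of large amplitude (a factor of several, since whole regions switch class).
The repair model is therefore: *the series is locally linear over a short
window; any sample deviating grossly from the local median is a failure and
carries no information about the true count.*

The default `mode="repair"` implements a Hampel detector followed by
interpolation, per channel (cuticle, body):

* rolling centered window (default `window = 5`, odd, min 3) gives the
  local median `med[i]` and the per-window median absolute deviation
  `MAD[i] = median(|w − median(w)|)` — computed within each window, not as
  a rolling median of a deviation series, which would be contaminated next
  to the spikes it is meant to detect;
* slice *i* is an outlier iff
  `|x[i] − med[i]| > 3 · 1.4826 · MAD[i]` **and**
  `|x[i] − med[i]| > 0.2 · max(|med[i]|, 1)`;
* maximal runs of outliers are replaced by linear interpolation
  (`np.interp`) between the nearest clean slices on either side; clean
  slices are never modified; finally the cuticle channel is clamped to the
  body channel.

The two-part rule separates regimes by amplitude. Genuine closure failures
change counts by tens to hundreds of percent. Legitimate slice-to-slice
variation has two components: the smooth profile itself (absorbed by the
rolling median) and voxelization ripple, which scales like 1/r of the local
count and stays near or below 10 % even for small cross-sections. The
relative floor of 0.2 sits between the two, so clean series pass through
bit-identical while injected spikes of factor ≥ ~1.3 at the detector's MAD
scale are removed. The floor exists because integer count series have tied
values: windows on a plateau have `MAD = 0`, and without the floor any
nonzero deviation there — including real curvature — would be flagged.

**Exactness regime.** On a locally linear series (constant integer step),
the rolling median of a clean window equals the true value and
interpolation from the flanking clean slices reproduces the line exactly,
so repaired width-1 and width-2 spikes (window 5) leave the series — and
hence the integrated volumes — bit-identical to the clean series. This is
the claim tested in `tests/test_acceptance.py`. On curved profiles
(e.g. a sphere's quadratic count series) the repair is instead bounded: the
relative volume error left by a repaired spike is below 10⁻³ in the shipped
property test, not zero.

**Detectability limit.** A spike is only detected if its amplitude exceeds
`max(3 · 1.4826 · MAD, 0.2 · local level)`. A width-2 spike occupies two of
five window samples — the breakdown point of the MAD — so small-amplitude
width-2 spikes near steep ramps can mask themselves. The validation
injects spikes of factor 4–12 (300–1100 % deviations), far above this
limit; callers repairing subtler artefacts should widen the window.

`mode="median"` applies a plain centered rolling median (edges computed on
the truncated window), for callers who want classical smoothing semantics;
note it perturbs every non-flat sample by design.

### Integration

`integrate_volumes` sums counts and multiplies by the voxel volume `p³`
(pixel size in µm, isotropic voxels). Scan metadata may give the pixel size
directly or via the scanner's magnification table
{10×: 1.22 µm, 5×: 2.44 µm, 2×: 6.11 µm}; both routes are tested to agree
exactly.

## 4. Height-step stitching (`stitcher`)

Tall specimens are scanned in overlapping height steps. `find_overlap`
tries every candidate overlap length from `min_overlap` up to the shorter
series, scoring each alignment by the mean absolute difference over the
aligned cuticle and body counts jointly; the minimum-score alignment wins,
ties going to the longest overlap. On noiseless data the true overlap
scores exactly 0. `merge_series` concatenates at the matched offset,
taking the first series' values on the overlap (`combine="first"`) or the
mean of both (`combine="mean"`). Noiseless split → merge round trips are
exact; with independent default-level degradation of each step, the true
offset is still recovered (acceptance keys
`stitch_roundtrip_max_abs_count_diff = 0`,
`stitch_offset_abs_error_slices = 0`).

## 5. SMA allometry (`allometry`)

Standardized major axis regression treats both variables as measured with
error, which ordinary least squares does not; its slope is the ratio of
standard deviations signed by the correlation:

```
b = sign(r) · s_y / s_x
```

with 100(1−α) % confidence interval `b · (√(B+1) ± √B)`,
`B = F₁,ₙ₋₂(1−α) · (1−r²)/(n−2)`. The implementation is tested against
this moment form on 1000 random datasets to 10⁻¹² relative, together with
the symmetry `b(x,y) · b(y,x) = 1` and the zero sum of SMA vertical
residuals.

* `test_slope_equals(fit, b0)` tests H₀: β = b0 via the correlation of the
  rotated variables `y − b0·x` and `y + b0·x`, which is zero under H₀;
  the statistic is the usual correlation t with n−2 df. Its type-I error at
  α = 0.05 is measured at 0.052 (n = 500, 1000 replicates, exchangeable
  construction with true slope exactly 1).
* `test_common_slope(fits)` tests slope homogeneity across groups by the
  likelihood-ratio heterogeneity statistic minimized over the common slope,
  with Bartlett correction, against χ² with (groups − 1) df;
  `method="permutation"` compares the same statistic to group-shuffled
  replicates instead.
* `species_means` collapses specimens to one record per species × caste
  (arithmetic mean by default, geometric via `log_then_mean=True`);
  `standardized_investment` fits log10 cuticle vs. log10 body volume for
  one caste and returns the vertical residuals as size-standardized
  investment; `caste_correlation` correlates those residuals across castes
  on matched species; `compare_to_reference` validates automated volumes
  against an independent table by r² of volumes and of cuticle/body ratios.

## 6. Synthetic phantoms (`phantoms`)

Ground truth must be exact, so phantoms are defined analytically and
rasterized by **voxel-center membership**: a voxel belongs to a region iff
its center satisfies the region's inequalities. The per-slice truth counts
are then sums over the same masks used to render the image — truth and
image cannot disagree. Voxel-center counting converges on the analytic
ellipsoid volume (within 2 % at radius 18, tested).

* `make_hollow_shell_stack`: a hollow ellipsoidal shell (semi-axes and
  thickness in voxels) rendered at three 16-bit gray levels — background
  5 000, interior tissue 12 000, shell 30 000 — chosen to mimic the
  ethanol/soft-tissue/cuticle contrast ordering of a real scan.
* `make_ant_like_stack`: three overlapping hollow lobes (head, mesosoma,
  gaster) along the stack axis, so slices include multi-contour and nested
  cases. `gap_fraction > 0` removes an angular sector of the gaster shell,
  producing genuinely open cross-sections; the truth is then flagged
  `body_approximate`, since "inside" is ill-defined for an open surface.
* `embed_in_vial` draws a bright ring (default 55 000) around the specimen
  without touching any specimen voxel, so truth counts are unchanged.
* `degrade` adds Gaussian noise and Gaussian blur. The documented default
  level — `noise_sd = 800` (≈ 4 % of the 18 000-level shell/interior gap)
  and `blur_sigma = 0.8` voxels (sub-voxel optics blur) — is the condition
  under which the 2 %-of-truth robustness envelope is stated and measured.
* `inject_spikes` multiplies chosen slices of a count series by given
  factors (width 1 or 2), returning corrupted and clean copies, for testing
  the repair.
* `split_height_steps` cuts a stack or series into overlapping steps whose
  overlapping slices are identical, for testing the stitcher.

### Phantom validation protocol

Noiseless phantoms are segmented with `SegConfig(min_perimeter=0)`. The
speckle cutoff of 40 px is calibrated to full-resolution scans (thousands
of pixels across); phantoms are rendered at a fraction of that scale, so a
genuine pole-cap cross-section of a small shell falls below 40 px, and a
noiseless render has no speckle to remove in the first place. Degraded
phantoms use the full default `SegConfig()` — noise creates exactly the
speckle the filter exists for. This protocol is fixed in
`tests/conftest.py` and stated in the acceptance-test docstring.

## 7. Numerical choices

* All count arithmetic is exact (integer masks summed; float64 series).
* No unseeded randomness anywhere: phantom generation, degradation and the
  permutation test take explicit seeds; 1-D k-means is deterministic by
  construction; `scripts/acceptance.py` derives every stream from `--seed`
  via `numpy.random.Generator.spawn`.
* The Hampel MAD is computed per window with `rolling.apply`; the cheaper
  rolling-median-of-deviations shortcut is wrong near window edges and near
  the very outliers being detected, and is deliberately not used.

## 8. Limitations

* **Open surfaces.** For shells with `gap_fraction > 0` the enclosed-body
  truth is approximate (flagged), and the hull/linking closures recover the
  morphologically plausible region, not a uniquely defined one.
* **Repair exactness is regime-bound.** Bit-exact spike removal holds for
  locally linear count profiles and spike widths up to (window−1)/2;
  curved profiles incur a small (≤ 10⁻³ relative, tested) residual, and
  spikes below the detectability limit in §3 are passed through.
* **Vial detector assumptions.** The rim must be the brightest structure,
  roughly centered, ring-like and large (≥ 60 % of the frame when filled).
  Off-center or cropped vials fall back to no-vial behavior, which is safe
  but forfeits the rim exclusion.
* **Threshold model.** The k-means band threshold assumes at most three
  intensity classes with the cuticle densest. Heavily stained preparations
  or metal inclusions brighter than cuticle would need an explicit `t_hi`.
* **Resolution.** Accuracy statements are measured on phantoms tens of
  voxels across; voxelization ripple shrinks with size, so they are
  conservative for full-resolution scans of the same geometry, but no claim
  is made for specimens only a few voxels wide.
* **SMA inference.** Confidence intervals and tests assume independent
  species-level observations with roughly bivariate-normal log volumes;
  phylogenetic non-independence is out of scope.
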