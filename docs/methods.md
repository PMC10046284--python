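# Methods

## Scoring model

The measurement model is Beer–Lambert absorption under brightfield
illumination.  With blank-glass intensity `I0` (default 255 per channel)
and a small offset `eps` (default 1 gray level, so the logarithm stays
finite at fully absorbed pixels), per-channel optical density is

    OD_c = -log10((I_c + eps) / (I0_c + eps)),   clipped at 0.

Optical densities of co-localized stains add, so `OD = M^T d` for stain
densities `d` and the stain matrix `M` whose rows are the unit-norm
absorbance vectors.  The shipped H-DAB preset uses the canonical published
constants — hematoxylin (0.650, 0.704, 0.286), eosin (0.072, 0.990,
0.105), DAB (0.268, 0.570, 0.776) — stored in a versioned YAML config so
alternative presets are drop-in.  Stain vectors are never estimated from
the image; when only two are supplied the third row is completed as the
non-negative re-normalized cross product.  Negative unmixed densities are
clipped to zero by default (they are physical concentrations); clipping
can be disabled for diagnostics.

Intensity is measured on the grayscale-inverted re-rendering of the DAB
channel — render `I_c = I0_c · 10^(-v_c d)`, average channels, invert —
rather than directly on the raw density channel, mirroring the protocol's
step order.  A direct-density mode exists for diagnostics only.  The
grayscale conversion defaults to the unweighted channel mean; luminance
weights are available by configuration and the choice is recorded in every
per-sample score.  On a noiseless slide the composite map from DAB density
to measured intensity has the closed form

    f(d) = 255 · (1 − mean_c 10^(−v_c d)),

strictly increasing in `d`; this is the oracle the tests check the
pipeline against and the map the phantom calibration inverts.

ROI statistics use the sample (n−1) standard deviation.  Every pixel
inside an annotated region is measured — including tissue-free holes such
as empty fat vacuoles — and no correction for cell density is applied;
both are deliberate properties of the protocol being implemented, not
omissions.  TBR is the tumor mean divided by the adjacent-healthy mean; a
zero background mean is an error (undefined), not infinity.

## Annotations and rasterization

Annotations are GeoJSON FeatureCollections of labeled polygons in pixel
coordinates.  A pixel belongs to a region iff its center `(x+0.5, y+0.5)`
lies inside the polygon union (even-odd rule) — deterministic and
independent of vertex order and orientation.  Multiple polygons per label
are unioned; interior rings (holes) are rejected as unsupported; tumor
and background masks must be disjoint and non-empty.  Tests verify the
rasterizer against a brute-force ray-casting scan and check the convex
boundary-band bound (raster area within one perimeter of analytic area).

## Cohort statistics

Patients with several samples get unweighted means of their per-sample
tumor and background intensities; the patient TBR is recomputed from the
averaged means rather than averaging per-sample ratios, so one patient
contributes exactly one value per comparison.  Tumor vs background within
patients uses a paired two-sided t-test; subgroup comparisons (with vs
without preoperative therapy) use the pooled-variance unpaired t-test by
default, with Welch available by flag since nothing in the protocol fixes
the variance assumption.  Significance is p ≤ 0.05, two-sided, with no
multiple-testing correction.  A biomarker counts as "expressed" in a
patient when the tumor mean reaches 10 on the 0–255 inverted scale; the
criterion is inherently arbitrary, so it is explicit configuration rather
than a hidden constant.  The t statistics are computed from explicit
sums; only the t distribution's tail function comes from scipy, and tests
cross-check both tests against brute-force formulas (1e−10) and scipy's
reference implementations.

## Synthetic cohorts

The generator exists because annotated IHC cohorts with adjacent healthy
tissue are effectively never public.  Each phantom is a 512×512 (default)
tile with a central elliptical tumor (semi-axes ≈ 0.29/0.23 of the short
side), a 4-sector annular healthy region, and a ~10-pixel unannotated
border band between them, mimicking a drawn tumor-border line.  The DAB
density is constant per region plus a seeded mid-frequency texture field
(white noise smoothed with a Gaussian of σ = 2% of the tile side,
normalized per region); hematoxylin is a uniform counterstain at density
0.3.  Pixel noise is Gaussian in OD space (default SD 0.03 OD, i.e.
multiplicative in intensity).  White disc-shaped "fat vacuoles" replace
5% of the healthy region by default and are forced to blank glass; they
stay inside the measured mask.  All stochastic elements derive from one
integer seed per slide, and regenerating from the same spec is
bit-identical.

Each preset case fixes two targets: the tumor-region mean and the TBR on
the inverted-grayscale scale.  Calibration inverts the noiseless closed
form `f` per region with bracketed root-finding (tolerance 1e−6 on
intensity, density ceiling 10 OD — targets at or above `f(10) ≈ 254.8`
are unattainable and raise an error naming the ceiling).  Because the
texture moves the region mean through the concavity of `f`, mean density
and texture amplitude are solved jointly: an inner root-find pins the
mean for a trial amplitude, an outer root-find pins the within-region SD
(tumor targets 39/45/36 by biomarker; background SD scaled by the
intensity contrast).  Vacuole pixels (intensity 0 after inversion) are
part of the calibration sample, so the background mean target is hit
including the holes.  Calibration uses at most 20 000 region pixels
(deterministic stride); the residual from sub-sampling is well under a
gray level.

The three presets encode a 17-patient cohort with an 11/6
preoperative-therapy split and fixed deterministic per-case target lists
(not sampled).  Subgroup means are exact by construction — TEM-1
85/74 intensity and 3.5/2.2 TBR, VEGF-A 96/73 and 2.7/1.8, PDGFR-α 70/52
and 1.9/1.5 — which implies overall means of 81.1/3.04, 87.9/2.38 and
63.6/1.76; the overall and subgroup summary values cannot both be exact
simultaneously, and subgroup exactness was chosen because the subgroup
tables carry the finer-grained information.  TEM-1 keeps every case above
TBR 1 (smallest 1.05); VEGF-A and PDGFR-α each contain exactly three
cases with TBR < 1.  The spread of the per-case lists is heuristic
("intensities vary greatly between cases") and chosen so the subgroup
comparisons are non-significant while the paired tumor-vs-background
contrast is strongly significant — properties of the cohorts being
emulated.

## What the phantoms do and do not show

Passing the recovery tests shows that deconvolution, rendering,
rasterization, ROI statistics and aggregation together invert the forward
model to within ~1–2 gray levels per case under realistic noise,
texture, vacuoles and quantization — i.e. the pipeline math is right and
its biases (the `eps` offset, noise rectification through the concave
intensity map, quantization) are small.  It does not show robustness to
features the phantoms lack: stain-vector mismatch between scanner and
preset, uneven illumination, section-thickness gradients, chromatic
artifacts, or morphologically structured staining.  Real-slide accuracy
additionally depends on annotation quality, which is an input here.

## Numerical choices and edge cases

- `eps = 1` intensity unit and `i0 = 255` per channel by default; a
  continuous-valued (non-quantized) image mode exists solely so oracle
  tests are not limited by 8-bit rounding. All production paths are 8-bit.
- Deconvolution linearity holds before negative-clipping; tests check it
  there.
- Degenerate inputs fail loudly: double inversion, empty or overlapping
  masks, zero-variance t-tests, singular stain matrices (the offending
  vector pair is named), unattainable calibration targets.
- A single-pixel ROI reports SD 0 with a warning rather than NaN.
- Constant rasters render at the colormap midpoint with a warning in
  gradient maps; scaling bounds are recorded in the output.
- Problem sizes: the bundled validation runs use 512×512 tiles for the
  full cohorts and 96–256 px tiles for unit-level checks; at 512×512 a
  region holds 5×10⁴–10⁵ pixels, so the standard error of a region mean
  is ≲ 0.2 gray levels and recovery tolerances are dominated by the
  deterministic biases above.

## Known limitations

- No stain-vector estimation (Macenko-style SVD); mismatched presets are
  not detected.
- No whole-slide pyramid formats; tiles only.
- Polygon holes are unsupported; annulus-like regions must be expressed
  as sector polygons.
- The expression-call threshold is a configuration convention, not a
  validated cutoff.
- Phantoms are statistical, not morphological (see above).
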