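# Methods

## Scope and model

The package quantifies three physiological characteristics of developing
apple fruitlets — spectral band-ratio indices from diffuse Vis/NIR
reflectance, trichome density from tape-peel micrographs, and chlorophyll
from spectrophotometric absorbance — and relates them statistically to fruit
size.  Because no field data ship with the package, a synthetic-cohort
generator reproduces the statistical structure of a two-cultivar
('Fuji', 'Honeycrisp'), two-date field campaign; every downstream stage is
validated against the generator's ground truth.

## Reflectance spectra and indices

Spectra live on a fixed grid of 266 wavelengths, 303–1098 nm in 3 nm steps
(the instrument's stated 3.3 nm "resolution" is read as optical bandwidth;
only a 3 nm sampling step yields 266 points on that range, and the grid
decision follows the printed point count).  Two indices are computed as
ratios of band means over closed intervals of grid points:

* CCI = R(522–579) / R(640–700) — chlorophyll concentration index,
* PWI = R(950–970) / R(890–900) — plant water index.

Band intervals include their endpoints; [640, 700] selects the grid points
642–699 because 640 and 700 are off-grid.  Both indices are invariant under
uniform scaling of a spectrum.  Standardization for PCA uses per-wavelength
z-scores with the n−1 standard deviation; a zero-variance wavelength is an
error, reported by wavelength.  Input spectra on a different wavelength grid
are linearly interpolated onto the canonical grid with a warning rather than
rejected.

## Trichome quantification

A tape strip lifts trichomes from calyx to pedicel; the micrograph is
thresholded (pixel ≥ threshold → trichome) and percent coverage is measured
in three 1.75 mm × 7.00 mm (12.25 mm²) rectangles whose centres sit at
fractions 1/6, 1/2 and 5/6 of the strip's long axis — the simplest layout
consistent with "equidistant" rectangles near the calyx, centre and pedicel.
Coverage is normalised per subsection (the 12.25 mm² basis), not per whole
image.  ROI dimensions round to the nearest pixel; at the reference
calibration of 4.43×10⁻⁶ mm² per pixel the pixel-rounded area differs from
12.25 mm² by < 0.1 %.  The default threshold is the fixed midpoint 128,
which is exact for the generator's two-level images (foreground clipped to
≥ 180, background to ≤ 80); an Otsu mode and an `--invert` flag serve real
micrographs of either polarity.

## Chlorophyll

Absorbance triplets at 664.1, 648.6 and 750.0 nm enter the standard
two-wavelength equations (coefficients 13.36/5.19 and 27.43/5.19, dilution
factor 1.45 mL), with the 750 nm reading as turbidity baseline.  The
equations are implemented literally as printed, labelled µg g⁻¹ DW; a
dimensionally complete account would also divide by the 0.02 g extracted
subsample mass, available behind the `mass_normalize` flag.  (The unit chain
is documented here, not silently "fixed": the default output matches the
printed equations.)  Negative concentrations are returned with a warning
rather than clamped, so bad readings surface.  Total content (µg) is
concentration × dry mass; water content is 100·(fresh − dry)/fresh.

## Synthetic cohorts

The four default cohorts mirror the field design: Fuji at 23 DAFB
(n = 47, 0.19–1.65 g) and 36 DAFB (n = 45, 2.10–10.30 g); Honeycrisp at
20 DAFB (n = 36, 0.17–0.88 g) and 29 DAFB (n = 29, 0.48–2.86 g).  Weights
are uniform on those ranges (only ranges are reported; uniform is the
simplest consistent choice).  Reported fruit counts are internally
inconsistent in the source material (47+45+36+29 = 157, a stated total of
158, and a combined PCA on 155); the generator keeps the per-cohort counts
and `default_pca_spectra` drops the last two fruit of the second Fuji cohort
to form the 155-spectrum PCA set.

Biology:

* **Dry weight** = intercept + slope·fresh, slopes 0.132 (Fuji) / 0.124
  (Honeycrisp), multiplicative Gaussian noise (relative sd 0.056 / 0.10).
  The intercept is solved per cultivar over both of its date cohorts so the
  expected water content is 85 % (for a uniform weight on (lo, hi),
  E[1/w] = log(hi/lo)/(hi−lo)); a single line per cultivar matches the one
  pooled regression the analysis stage fits.
* **Chlorophyll concentration** = intercept + slope·fresh, truncated at
  zero, with intercepts 1100 / 850 µg g⁻¹ DW (the ~250 cultivar offset) and
  a shared slope of −60 µg g⁻¹ DW per g; multiplicative noise of relative
  sd 0.10, calibrated once so the Fuji content–weight Pearson r ≈ 0.944.
  Chlorophyll a is a fixed 0.74 share of total.
* **Trichome coverage** per position is linear in weight with the calyx line
  steepest: Fuji 45 − 4.0·w (calyx), 26 − 1.5·w (centre), 32 − 2.0·w
  (pedicel), crossing calyx = pedicel at 6.5 g; Honeycrisp 50 − 8.0·w,
  30 − 1.8·w, 35 − 2.0·w, crossing at 2.5 g.  Additive noise (sd 10 / 5
  points) is truncated to [0, 100].

Spectra come from a lens-coverage mixture: the fruit covers a fraction
f = min(1, (w/w_sat)^(2/3)) of the fixed lens (cross-section ∝ weight^(2/3)),
saturating at w_sat = 5.0 g (Fuji) / 2.25 g (Honeycrisp), and the reading is
f·R_tissue + (1−f)·R_bg with R_bg = 0.35 a.u.  Tissue reflectance is a
smooth monotone (PCHIP) template through fixed control points — UV edge
0.12, peak 0.55 at 425 nm, green trough, NIR plateau 0.85 — attenuated by
Gaussian absorbers:

* chlorophyll: G(430, 30) + G(600, 45) + G(675, 25).  The 600 nm band forms
  the observed 560–640 nm reflectance minimum; the 675 nm band is the red
  chlorophyll-a absorption, and it is what makes CCI *increase* with
  chlorophyll (without it the green-trough band hits the CCI numerator
  harder than the denominator and the index runs the wrong way);
* water: G(975, 25) with optical depth k_w·f·(w_sat/max(w, w_sat))^1.5
  (k_w = 0.30) — unimodal in weight so the PWI–weight curve bottoms out at
  lens saturation.

Chlorophyll optical depth is 1.8×10⁻³ per µg g⁻¹ DW times an areal-dilution
factor (w_sat/max(w, w_sat))^0.40: past lens saturation, expanding
water-filled cortex cells dilute chlorophyll along the optical path faster
than per-dry-mass concentration declines.  Without this term the fitted CCI
vertex sits systematically ~0.4 g above the saturation weight.  A
backscatter gain w^0.14, ramped in logistically above ~750 nm, makes the NIR
plateau keep rising with fruit size (as observed between sampling dates)
while leaving the visible region absorption-dominated; because the ramp is
flat across both PWI bands and absent from both CCI bands, it cancels in the
indices.  Intact fruit get a small broadband trichome term
(0.05 × mean coverage fraction); "removed" spectra omit it.  Measurement
noise is a lognormal per-spectrum amplitude jitter (sd 0.005) plus additive
white noise (sd 0.001 a.u.), small because the instrument averages and
dark-corrects internally.

Micrographs are rendered as randomly placed and oriented bright fiber
segments (~1 mm long, 2–3 px wide, intensity 230 ± 10 clipped to ≥ 180, on
background 20 ± 5 clipped to ≤ 80) added until the target pixel fraction is
reached, on a canvas padded by one fiber length and cropped so density is
stationary to the image border (unpadded rendering depletes the edges and
biases the interior ROIs upward by ~1 point).  A (calyx, centre, pedicel)
target triple fills each third of the strip separately.  The exact rendered
mask ships with the image as ground truth.  The default synthetic geometry
is 480 × 360 px at 0.025 mm/px (the 1.33 aspect of the reference images at a
tractable resolution).

Absorbance triplets invert the 2×2 chlorophyll system (determinant
13.36·27.43 − 5.19² = 339.5287, comfortably conditioned) for the
turbidity-corrected differences, with the 750 nm baseline at 0.01 and
optional Gaussian reading noise (sd 0.003).

All randomness descends from one seed per cohort through spawned child
streams (biology, spectra, images, absorbance), so record tables are
identical whether or not images are rendered, and equal seeds give
byte-identical outputs.

### Calibration

The generator's linear trends come straight from the reported slopes,
ranges, offsets and crossing points.  The handful of invented-form constants
(absorber scale, areal-dilution and backscatter exponents, noise sds) were
calibrated once against the reference anchors in
`fruitlet.synthesis.REFERENCE_ANCHORS` — dry-matter slopes 0.132/0.124
(±0.01), mean water 85 % (±2), CCI vertex 5.0 g and PWI vertex 2.5 g (±0.5),
Fuji chlorophyll-content correlation 0.944 (±0.05), PC1 share 86.56 % (±5) —
and then frozen; a 20-seed sweep passes every anchor at every seed.
`fruitlet reproduce` re-derives the full table end-to-end.

### What the generator does not emulate

Real spectra have instrument-specific baseline structure, specular
artefacts, and anthocyanin absorption that the three-Gaussian model omits;
real trichome images have focus gradients, wax debris and uneven
illumination that break a fixed global threshold (use the Otsu mode); the
true unit chain of the chlorophyll equations is implemented as printed, not
re-derived.  Passing tests therefore demonstrate that the pipeline recovers
known structure of this statistical form, not that the model is an optical
simulation of fruit tissue.

## Statistical stage

PCA is the eigen-decomposition of the covariance of the standardized
spectra (equivalently the correlation matrix of the raw spectra), components
ordered by variance, explained percentages over all min(n−1, p) components
(so they sum to 100), and each loading vector oriented so its
largest-magnitude element is positive.  Regressions are OLS with intercept;
the cultivar comparison fits y ~ x + group + x:group and reads the slope
difference off the interaction coefficient's two-sided t-test.  The
quadratic fit reports the vertex −b/(2a), a maximum iff a < 0.  The
correlation matrix is pairwise-complete Pearson with two-sided p from the
t transform on n−2 df and conventional stars (0.05/0.01/0.001); no
multiple-testing correction is applied, matching the analysis it mirrors.
Implementation rides on scikit-learn (PCA), statsmodels (OLS) and scipy
(correlations) behind the package's interfaces.

## Numerical choices and degenerate inputs

Empty bands, zero denominators, zero-variance wavelengths, out-of-bounds
ROIs, undersized images, dry > fresh weights, non-finite absorbances,
constant-x fits and < 3 complete correlation pairs all raise explicit
errors (or, for correlations, flag the entry missing) rather than
propagating NaNs.  Coverage targets above 95 % are rejected as unreachable
for the fiber renderer.  The problem sizes throughout (157 fruit, 266
wavelengths, 480 × 360 px images) keep the full suite and the acceptance
script in the seconds-to-a-minute range on one core.

## Known limitations

The PC1-versus-weight rank correlation across the pooled cultivars is
structurally limited by the differing saturation weights (a 2.5 g Honeycrisp
fills the lens; a 2.5 g Fuji does not), and sits near 0.93 under the default
conditions.  The post-saturation PWI rise is a descriptive stand-in (its
mechanism is not established), as is the areal-dilution exponent.  The
interaction and polynomial fits assume homoscedastic errors; the generator's
multiplicative noises mildly violate this, as real data would.
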