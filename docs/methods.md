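# Methods

`platequant` turns a top-view photograph of a white 96-well microplate
into per-well optical densities and dilution-corrected biomarker
concentrations. This note records the measurement model, the synthetic
scene model used to validate it, the numerical choices, and the known
limits of what the synthetic tests demonstrate.

## Measurement model

**Registration.** The device carries four near-black square fiducials
around the plate. They are segmented from the channel-maximum image at
half the median image brightness — the channel maximum separates
neutral-dark fiducials from dye, which is dark only in its absorbed
channels — filtered by solidity (> 0.8) and area (within 0.25–4x the
expected fiducial area), and assigned one per image quadrant. Each
centroid is refined to sub-pixel precision with a darkness weight
normalised against the local background, so anti-aliased edge pixels
contribute fractionally and the smooth illumination gradient across a
mark does not bias the centroid. Four correspondences to the configured
canonical positions determine the pixel→mm projective homography
exactly (8 constraints, 8 dof, direct linear transform). Test and white
images are rectified into the canonical frame (origin at the plate's
top-left corner, x right / y down, mm; ANSI/SLAS grid: 9 mm pitch, A1
at 14.38 mm, 11.24 mm) by bilinear resampling at 4 px/mm; pixels that
sample outside the source are masked and never enter a histogram.

**Flat-field.** The white-block image, aligned with the same transform,
is Gaussian-smoothed (sigma = 2 % of image width — wide enough to kill
target texture and sensor noise, narrow relative to the illumination
field) and inverted into a per-pixel, per-channel gain
`gain = median_ch / white_smoothed`. Median (not max) normalisation is
robust to specular highlights. The model is multiplicative only: one
white exposure cannot separate a dark offset, which is negligible for a
well-exposed camera. Builds fail loudly when > 1 % of a channel is
saturated or the max/min gain ratio reaches 10.

**Well readout.** Each well's ROI is the concentric disc at 70 % of the
well radius — inside the wall and rim shadow. Per channel, the readout
is the histogram mode over the 256 integer intensity levels (ties break
to the lower level). The mode is the glare/bubble-robust statistic: any
artefact that leaves the majority of ROI pixels untouched cannot move
it. The three channel modes combine into one scalar
`y = a·I_R + b·I_G + c·I_B`, where (a, b, c) are the camera's RGB
sensitivities at the assay's peak absorbance wavelength, normalised to
sum to one. Presets: creatinine 490 nm (RS, GS, BS) = (0.07, 0.82,
0.66); glucose 560 nm (0.13, 0.83, 0.11); other wavelengths come from a
user-supplied sensitivity curve by linear interpolation.

**Incident light and OD.** Empty wells stay at the unabsorbed
illumination level, so the most frequent integer-rounded y across the
96 wells (ties to the brighter bin) is the global empty-well level w.
Each well's local incident estimate wL is the mean of the intensities
≥ 0.95·w within its 5×5 well neighbourhood (truncated at the plate
edges; the centre well is included — a filled centre fails the 0.95·w
cut anyway). If no neighbour qualifies, wL falls back to w and the well
is flagged. Then `OD = −log10(wL / y)`: the device's sign convention,
under which an absorbing solution has OD ≤ 0. The `conventional_od`
flag flips the sign to textbook absorbance; fitted curves record which
convention they were built under.

**Quantification.** Calibrator concentration relates exponentially to
OD, so the curve is ordinary least squares of ln C on OD:
`ln(Cd) = x·OD + z`. The zero calibrator is excluded from the log fit
(ln 0 undefined) but kept for QC — its OD should sit near 0 — and it
anchors the low end of the reported concentration span. Predictions
apply `Cd = exp(x·OD + z)` and `C = Cd·df` (df = fold dilution, exact
multiplication). Flags, never failures: `above-range` / `below-range`
compare Cd against the assay's detection range, `extrapolated` marks
ODs outside the fitted standards' span. Replicates report the mean and
sample SD (n−1; for duplicates `|x1−x2|/√2`). The dilution-series
report recommends the in-range dilution level with the smallest
replicate SD (ties to the lowest factor): stronger dilution stabilises
high-concentration samples until Cd drops out of range. The curve's
steepness `|dC/dy| = C·|x| / (y·ln 10)` grows monotonically with
concentration — the quantitative form of the observation that a fixed
intensity perturbation moves high-range results far more than mid-range
ones, and the reason the dilution advisory exists.

## Synthetic scene model

The generator is the test bed for every stage; its defaults are the
study conditions of the test suite and of `scripts/acceptance.py`.

* **Geometry.** ANSI/SLAS plate (127.76 × 85.48 mm), 8×12 grid, well
  radius 3.4 mm; 6 mm fiducial squares near the plate corners. Exact
  fiducial placement on the original device is not published; positions
  are configuration, not constants.
* **Dye.** Per-channel transmittance `10^(−s·alpha_ch)` with
  absorptivities normalised so the absorbance-wavelength channel has
  alpha = 1 (creatinine: (0.08, 1.0, 0.80), a red complex; glucose:
  (0.12, 1.0, 0.30), pink). The scalar s is solved per well (Brent's
  method, bracket [A, A/alpha_min]) so the *weighted* intensity obeys
  `y = y_blank·10^(−A(c))` exactly, giving an analytic oracle for the
  OD and curve stages. The concentration→absorbance response is
  configurable: `log_linear` (default for the shipped assays,
  `A = (z − ln c)/x`, mirroring the empirically exponential standard
  curves of the real kits and making ln C exactly linear in OD) or
  `beer_lambert` (`A = k·c`).  Shipped parameters: creatinine
  x = −2.5, z = −2.0 (absorbance 0.20 at the 0.221 mmol/L standard,
  1.03 at 1.77 mmol/L); glucose x = −4.0, z = −0.7.
* **Illumination.** Four corner sources with
  `I_i / (1 + (d/45 mm)^2)` falloff, normalised to 1 at the brightest
  plate point. This produces a ~25 % corner-to-centre gradient (empty
  well CV ≈ 9 % uncorrected), strong enough that skipping the
  flat-field stage visibly breaks the readout.
* **Camera.** Homography at 5 px/mm with 1.5° rotation and perspective
  terms (2.5e-4, 1.5e-4) mm⁻¹ — a mildly off-axis camera scaling the
  far plate edge ~4 % smaller — so all eight homography degrees of
  freedom are exercised and identifiable from four fiducials. Image
  704×480, 8-bit, round-half-even quantisation. Fiducial edges are
  rendered with analytic coverage (anti-aliased); well discs are
  hard-edged, which the mode readout does not notice.
* **Noise and artefacts.** Per-channel Gaussian sigma 2 (on the 0–255
  scale), 4 saturated glare discs of radius 0.5–1.2 mm (each covering
  ≤ 20 % of a well) and 2 bubbles (0.4–0.8 mm, ×0.6 attenuation) placed
  randomly inside wells. All randomness flows from one integer seed;
  identical specs render bit-identical images.

**What the generator does not emulate:** lens distortion and PSF, Bayer
demosaicing, liquid meniscus optics, well-to-well reagent variability,
urine background colour, and temporal drift of the LEDs. Passing
synthetic tests therefore demonstrates the correctness of the
*algorithmic chain* under controlled optics, not the clinical accuracy
of any physical device; the clinical comparison statistics reported for
the original instrument require patient samples and hardware and are
out of scope here.

## Problem sizes and numerical choices

* Held-out recovery (the acceptance benchmark) uses 20 seeded plate
  replicates at 704×480 render / 4 px/mm rectification — about 0.5 s
  per replicate — treating the 0.221 mmol/L calibrator as unknown and
  fitting on the remaining five nonzero standards (extrapolating one
  step below the fitted OD span, which the exact log-linear response
  tolerates). Typical median recovery error is ~1 %.
* Histogram modes use exactly 256 integer bins; no re-binning, so the
  readout is format-exact for 8-bit sources.
* The well-level intensity histogram rounds real-valued y to the
  nearest integer level before voting, making "most frequent value"
  well defined.
* Homography estimation normalises coordinates internally
  (scikit-image DLT); the four-point fit is exact to machine precision,
  and the reported residual is the max reprojection error in mm.
* Degenerate inputs fail loudly with typed exceptions: < 4 (or > 4)
  fiducial candidates, collinear fiducials, saturated white images,
  ROIs with < 50 usable pixels, < 3 nonzero standards, zero OD
  variance. Saturated wells (mode 0) are flagged and skipped rather
  than propagating infinities.

## Known limitations

* The 0.95·w empty-well rule applies no role-based exclusion: a pale
  sample well close to the incident level could in principle enter the
  local empty set. On plates laid out per convention (standards in row
  A, samples mid-plate, generous empty wells) this does not occur.
* Quantisation to 8 bits bounds OD precision at roughly
  0.5/(y·ln 10); near the top of the creatinine range (y ≈ 20) this is
  ~1 % in intensity and ~2.5 % in concentration, which is the dominant
  error source on noiseless synthetic plates.
* The dilution advisory needs replicate SDs at ≥ 2 levels and assumes
  replicates share the plate and curve.
* Unit handling is assay-native (mmol/L for creatinine, mg/dL for
  glucose); the only built-in conversion constant is
  1 mg/dL creatinine = 0.0884 mmol/L.
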