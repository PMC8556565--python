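# Methods

## Scope and data model

The package analyses spectral-domain OCT BM-scan volumes of the mouse
retina: at each of `n_bscans` lateral positions, `n_repeats` consecutive
B-scans of `n_alines` A-lines are recorded.  The canonical in-memory object
(`OCTVolume`) is a nonnegative 4-D array `(bscan, repeat, depth, aline)`
with depth index 0 anterior (vitreous side), an axial pixel scale in
tissue, and a lateral pixel scale.  The study acquisition geometry is 512
BM-scans × 5 repeats × 512 A-lines over a field of view of roughly
0.8 mm; development and testing run a scaled raster of 64 × 5 × 400 × 128,
which preserves every geometric relationship (retina ≈ 200 µm ≈ 79 px at
2.53 µm/px) at about 1/30 the voxel count.  All boundary depths are float
pixels at the interface; a layer occupies the half-open interval
`[upper, lower)` and its thickness is `(lower − upper) × axial_scale_um`.

The axial scale in tissue is the native in-air sampling divided by the
tissue refractive index: 3.42 µm/px / 1.35 = 2.53 µm/px.

## The synthetic phantom

The phantom emulates what the segmentation relies on, with every parameter
exposed in `PhantomConfig`:

- **Layered reflectance.**  Anterior-to-posterior: vitreous (0.02), NFL
  (0.85), IPL (0.70), INL (0.30), a thin bright OPL band (0.65, 8 µm,
  centred on the INL/ONL interface), ONL (0.25), an IS/OS band (0.75,
  12 µm, ending at the RPE anterior edge), the RPE-Bruch complex (peak
  1.60) and a dim sub-RPE region (0.04).  Values are relative linear
  intensities chosen to reproduce the qualitative hyper/hypo-reflective
  alternation of rodent retina at 1300 nm, with the RPE-Bruch complex
  strictly brightest (the anchor of the segmentation).  Defaults layer
  thicknesses (18 / 52 / 30 / 85 / 15.2 µm) total ≈200 µm, the expected
  vitreous-to-RPE distance.
- **RPE band profile.**  The RPE-Bruch band carries a raised-cosine axial
  profile peaking at the band centre, so the brightest voxel of an A-line
  marks the band centre rather than an edge.  A flat-top band under SNR
  roll-off would bias the per-A-line argmax to the band's anterior edge.
- **Surface curvature** is a polynomial in the normalised en-face radius
  (default 10 px of sag), and an optional radial thickness gradient scales
  all layers with radius for the ONH band analyses.
- **Speckle.**  Multiplicative gamma-distributed intensity with shape
  k = 3 (partially developed speckle; contrast 1/√3 ≈ 0.58), the standard
  closed-form model that the tests verify directly.  Static tissue shares
  one speckle draw across the repeated frames — speckle is frozen when
  nothing moves — while voxels inside vessels get an independent draw per
  frame.  This produces temporal variance exactly where angiography
  expects it.  `speckle_shape=inf` disables speckle (ideal reflectance),
  the noise-free reference of several tests.
- **Roll-off and background.**  An exponential depth attenuation
  (0.9995/px) multiplies the noise-free signal before speckle; each frame
  receives independent additive exponential background noise (mean 0.01).
  Both model the depth-dependent sensitivity decay and the noise floor of
  a spectrometer-based system, and both are invertible by the
  preprocessing stage.
- **Vessels** are en-face disks (radius 4–5 px) at mid-NFL depth with
  dynamic speckle and a ×0.5 intensity shadow on everything beneath them.
- **ONH**: the outer bands (IS/OS and RPE) are suppressed ×0.15 inside a
  disk (radius 10 px at study scale), uniformly in depth — the disruption
  is quasi-cylindrical with no axial curvature.

What the phantom does **not** model: physical wave-optics (no coherent
point-spread function or lateral speckle correlation), polarisation,
motion other than rigid shifts, vessel networks/capillary plexuses, eye
curvature distortion of the lateral scale, or wavelength-dependent water
absorption.  Passing tests therefore demonstrate correctness of the
*algorithms* under realistic first-order statistics, not performance on
real acquisitions.

Spectral fringes for the dispersion stage are generated separately
(`make_fringes`): complex exponentials per reflector with a dispersive
phase `a₂(k−k₀)² + a₃(k−k₀)³` applied in the k-domain.

## Preprocessing choices

- **Dispersion compensation** multiplies by the conjugate phase and
  Fourier-transforms to depth; the peak width is measured as
  half-maximum-crossing FWHM on a zero-padded (oversampled) transform.
- **Background** is subtracted as a mean depth profile, not voxelwise: the
  background volume is acquired outside the field of view, so only its
  depth statistics generalise.
- **Roll-off correction** takes a known/user-fit decay; any positive decay
  is accepted so that the correction composes and inverts cleanly.
- **Registration** is rigid per-B-scan translation via FFT
  cross-correlation against the previously aligned B-scan, integer-pixel
  by default (subpixel via upsampled cross-correlation optional).  Match
  images are repeat-averaged and box-smoothed (5 px): neighbouring B-scans
  carry *uncorrelated* speckle, which otherwise competes with the anatomy
  for the correlation peak.  Constant images tie to zero shift.  Integer
  shifts are applied circularly, making the operation exactly invertible.

## Segmentation choices

Free design parameters (`SegmentationParams`) and their defaults:

- **Denoising**: rectangular averaging kernel of 3 (depth) × 11 (lateral)
  px, plus averaging over 5 adjacent B-scans.  Boundaries vary slowly
  laterally and across B-scans (they are smooth surfaces), so strong
  lateral averaging buys speckle suppression at negligible geometric cost;
  depth smoothing is kept minimal to preserve gradient localisation.
- **Axial masks**: the "linear mask" gates are hard windows between
  previously detected surfaces.  The squared-Hann weightings (window
  length 31 px) act as soft axial masks centred on prior depths: the
  expected OPL depth is a configurable fraction (0.5) of the local
  vitreous-to-RPE distance; the expected NFL posterior depth is a prior
  thickness (18 µm) below the surface.  If a search window is shorter than
  the Hann length the weighting is dropped.
- **Sub-pixel refinement**: every argmax/argmin is refined by a 3-point
  parabola through the extremum (offset clipped to ±0.5 px); ties resolve
  to the anterior-most depth.
- **RPE posterior** is the detected band centre plus a half-width of 3 px
  (the RPE-Bruch complex is treated as one layer).
- **ONH detection** projects the mean intensity in a ±3 px band around a
  robustly smoothed RPE surface; the largest connected region below 0.6 ×
  the median defines the disruption, its equivalent-circle diameter the
  ONH width, and the circumscribed circle the exclusion mask.  The
  smoothing for this step uses median/MAD-initialised iterated polynomial
  fits (a plain least-squares fit is visibly dragged by the compact run of
  in-ONH outliers), and the projection uses a lightly smoothed volume
  (3 × 3) so heavy lateral averaging cannot inflate the disruption
  footprint.
- **Artifact correction** fits a 4th-order polynomial per B-scan to each
  boundary; points more than 2 residual SD from the curve are replaced by
  the fitted value, NaNs are filled from the fit, and B-scans with too few
  valid points inherit the nearest B-scan's fit (flagged).  Order 4 tracks
  retinal curvature without chasing spikes.
- **Ordering** (vitreous ≤ NFL/IPL ≤ IPL/INL ≤ OPL ≤ OS ≤ RPE posterior)
  is enforced by clipping after correction, with a warning counting the
  clipped points.  ONH A-lines are NaN in every boundary and excluded from
  the fits.
- Detector-specific degeneracy rules: a window with no positive gradient
  returns NaN (pure vitreous) or collapses onto the anterior bracket
  (zero-thickness NFL); flat intensity profiles return the prior-dominated
  depth flagged low-confidence.  User-supplied prior depth maps
  (`prior_depths`) provide the semi-automatic override channel; defaults
  run fully automatically.

## Angiography choices

Temporal variance uses divisor N (population variance).  The
motion-robust variant evaluates every leave-one-out subset per BM-scan and
keeps the one with the lowest spatial-mean variance (ties drop the last
frame); by construction its spatial mean never exceeds the full-set value.
Frame removal is per BM-scan (whether the original procedure removed
frames globally or per BM-scan is not specified; per BM-scan is strictly
more flexible and is exposed through the API).  Vessel masks threshold the
en-face variance projection at mean + 2 SD and drop 8-connected components
smaller than 5 px.

## Morphometry choices

Layer definitions partition the total retina exactly: NFL =
vitreous→NFL/IPL, IPL = NFL/IPL→IPL/INL, INL = IPL/INL→OPL, ORL =
OPL→RPE posterior, total = vitreous→RPE posterior.  The OPL boundary is
the detected intensity-peak depth (whether the ORL should start at the
OPL's anterior or posterior edge is anatomically ambiguous; the peak
convention makes the INL/ORL split reproducible and conserves the total).
ROI placement is automated: among all centres whose 51 µm disk avoids the
vessel mask, the ONH mask and the field border, the centre maximising the
clearance to the nearest excluded pixel is chosen, ties to the smallest
(row, col) — reproducible where a manual choice would not be.  The ONH
band analysis uses 55 µm annuli adjacent to the ONH rim and inside the
field-of-view edge; overlapping bands are a hard error (such samples are
excluded from band analysis).

## Statistics choices

Quantiles use linear interpolation between order statistics throughout
(quartiles, fences, boxplot summaries).  The Kruskal-Wallis H is
tie-corrected with a χ²(k−1) reference; an exact permutation p-value is
available and enumerated exhaustively when the number of distinct group
assignments is below 2×10⁵.  All values identical yields H = 0, p = 1.
IQR outliers are flagged but never removed.  Bland-Altman limits use the
sample SD and a two-sided normal quantile; the "maximum difference at 90%"
is the larger magnitude of the two interval ends.  Linear mixed models
with Tukey-Kramer correction are deliberately out of scope — the thickness
table is exported long-form so external tools can fit them.

## Numerical notes

- Determinism: every stochastic element flows from a single
  `numpy.random.default_rng(seed)`; identical configuration and seed give
  bit-identical volumes, segmentations and tables.
- The acceptance script runs five phantoms at the 64 × 5 × 400 × 128 study
  scale plus 10⁴ null simulations in well under a minute on one CPU.
- The empirical type-I error of the χ²-referenced Kruskal-Wallis test at
  3 groups of 10 is ≈0.044 (10⁴ simulations): the asymptotic reference is
  slightly conservative at this sample size, which is why the test budget
  is |rate − 0.05| < 0.01 rather than pure binomial noise.

## Known limitations

- Tuned for healthy developing retinas with a detectable RPE band;
  degenerated or detached retinas violate the brightest-band and
  200 µm-prior assumptions.
- The choroid is not segmented and RPE is not separated from Bruch's
  membrane.
- Dispersion coefficients are user inputs (they depend on the optical
  system); no auto-calibration is provided.
- Lateral distances assume a uniform en-face pixel scale; no transverse
  curvature correction is applied.
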