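# Methods

This note documents the models behind `centistress`: what the phantom and
cohort simulator emulate (and deliberately do not), how the quantification
and calibration chain is constructed, the statistical machinery, the
numerical choices, and the known limitations.

## The phantom

The template is a voxelized label map on a regular isotropic grid (2 mm
voxels; 96³ by default for standalone use, 48³ for the default study
cohort) with seven labels: cortical target grey matter, deep grey matter,
cerebral white matter, cerebellar grey matter, cerebellar white matter,
brainstem/pons, and background (CSF/air).  Real anatomy is replaced by the
simplest geometry that preserves the *adjacency relations* that matter for
partial-volume effects, because adjacency is what determines the sign of
resolution-driven bias:

- A cortical grey-matter ribbon wraps a cerebral white-matter core, so the
  template-style cortical target (which overlaps white matter) and the
  subject-based target (which does not) differ in WM fraction.
- The cerebellum nests into the posterior-inferior cerebral mass, so
  cerebellar grey matter is bounded by cerebellar WM inside and mostly by
  cerebral tissue outside — only its lower cap faces background.  This
  mirrors the tentorial anatomy in which cerebellar cortex lies under
  occipital cortex, and it is what makes the CGM reference region *gain*
  signal as resolution coarsens (WM/cortex spill-in beats background
  spill-out).
- The pons sits below the cerebrum, largely surrounded by CSF, so it
  *loses* signal under smoothing — the strong resolution sensitivity of
  pons-referenced pipelines.

All geometry parameters (centres/radii as fractions of the half field of
view) are explicit in `PhantomSpec.region_geometry`; the builder rejects
overlapping, edge-touching or empty compartments.

### Uptake model

Intensities are piecewise constant per compartment, relative to cerebellar
GM = 1.  White matter takes the tracer's WM/reference ratio
`wm_uptake_base + wm_age_slope·(age − 70)`; the cortical target is scaled
so that the ideal (unsmoothed) target/WCB ratio equals the tracer's SUVr at
the subject's true CL, linearly interpolated between its 0-CL and 100-CL
anchor SUVrs and extrapolated outside.  Noise is multiplicative Gaussian
per region (default SD 2%, clipped at zero intensity).  Piecewise-constant
uptake keeps every SUVr analytically predictable, which is what makes the
exactness tests possible; it deliberately omits voxelwise texture,
off-target binding gradients and vascular structures.

Age enters *only* through white matter.  The default tracer profiles
(target SUVr range, WM ratio, WM age slope per year — PiB 2.10/0.002,
flutemetamol 2.00/0.0015, florbetaben 1.90/0.0070, florbetapir 1.70/0.0030)
were chosen so that the amyloid-negative ΔCL(pons − WCB) pattern has the
florbetaben ≪ florbetapir < flutemetamol ordering with magnitudes of a few
to ~15 CL; these magnitudes are configuration, not assertions, and the
tests check only the ordering and signs.

### Atrophy

`SubjectParams.atrophy` is the grey-matter volume retained relative to the
template (the subject's GM/TIV normalised to the template's).  Morphing
peels GM voxels from the CSF-facing surface inward — voxels sorted by
Euclidean distance to background, deterministic index tie-break — until the
target count is met exactly, relabelling them background.  This preserves
the GM/WM interface (sulcal widening happens on the pial side), is strictly
monotone in the atrophy parameter, and empties embedded structures last.
Requests that empty a required region raise a degenerate-subject error.

### Resolution and motion

The scanner point-spread is an isotropic Gaussian; the convolution kernel
is normalised to unit sum with periodic boundary handling, so total
intensity is conserved exactly (the phantom's background margin makes
wrap-around spill negligible).  Effective resolution accumulates in
quadrature, and harmonization smooths with the quadrature complement
`sqrt(target² − current²)` — an image already coarser than the target
raises a cannot-sharpen error.  Each subject also receives a small random
rigid subject-to-template transform (0.5 mm / 0.5° SD), applied when the
native-grid scan is rendered (trilinear); it is the "registration" the
MNI-space pipelines invert.

### Cohort defaults

The default cohort emulates a memory-clinic sample: 60 subjects, half
amyloid-positive (true CL ~ N(78, 25²) vs N(2, 10²); the 24-CL boundary
assigns the ground-truth group), ages ~ N(71, 6.7²) clipped to 50–90,
diagnoses SCD/MCI/dementia with stage-dependent atrophy (0.96/0.91/0.85
mean GM fraction), tracer allocation FMM 39% / FBB 23% / FBP 38%, native
FWHM uniform on 5–8 mm harmonized to 8 mm.  FMM and FBB subjects carry both
original and harmonized scans (64 measurements each); FBP subjects only
harmonized scans (32) — reproducing a pooled two-cohort structure.  The
amyloid-load distributions are stated assumptions of the synthetic design,
not estimates of any real cohort.  Per-subject RNG streams derive from a
SHA-256 hash of (root seed, subject id), so any subject subset reproduces
in isolation.

## Quantification

The 32 pipelines are the full factorial of reference region (WCB, CGM,
pons, WCB+BSTM) × RR delineation (template "GAAIN"-style vs subject-based)
× target delineation (idem) × space (MNI vs native), enumerated in a fixed
order.  GAAIN-style masks are template-label masks whose cortical target is
dilated one voxel into white matter, emulating a fixed template ROI that
overlaps WM and ignores individual atrophy; subject-based masks are the
subject's own exact tissue masks.  MNI-space quantification resamples the
image onto the template grid (trilinear) and keeps template-grid masks;
native-space quantification resamples masks (nearest neighbour) and keeps
the image.  Interpolation-induced smoothing is accepted as part of the
space effect.  SUVr is the ratio of mask means; it is invariant under
global intensity rescaling.

## Calibration

Calibration scans are simulated phantom images (flagged as simulated in the
bank): atrophy-free subjects at true CL 0, 25, 50, 75, 100, imaged with
both the tracer under calibration and the PiB anchor tracer at the 8 mm
harmonized resolution, with age ramping from 25 (young controls) to 70
(typical AD).  The young-control age matters: because white-matter uptake
grows with age, anchoring the scale on young controls while quantifying
elderly subjects is precisely what biases pons-referenced pipelines low,
by an amount ordered by each tracer's WM age slope.  For each (tracer,
pipeline) pair a level-2 conversion (OLS of PiB SUVr on tracer SUVr) is
fitted and validated against the standard criteria (r² > 0.70, slope > 0,
enough pairs); the CL scale is then anchored at the tracer's *converted*
0-CL and 100-CL group means, so both calibration groups map to exactly 0
and 100 CL for every pipeline by construction.  `CalibrationConfig.ideal()`
(equal ages, no PSF, no noise) defines the exactness baseline under which
the full chain returns true CL to machine precision and all 32 pipelines
coincide — the physical causes of between-pipeline spread (spill-in,
atrophy, motion, age mismatch) having been removed.

## Statistics

**Bias models.**  Measurements are clustered within subject (32 or 64 rows
each), so bias models are Gaussian identity-link GEEs clustered by subject.
The working correlation is exchangeable by default (repeated measures
within subject), with an independence switch for sensitivity; inference
always uses the robust sandwich covariance.  Factors are coded with
sum-to-zero contrasts, making the per-term joint Wald chi-squares Type III
and invariant to level ordering.  The four model builders mirror the
analysis plan: technical factors with tracer interactions; plus age, plus
atrophy (each interacted with the technical factors); plus harmonization
status, the latter fitted only on dual-image subjects.  Marginal means
average model predictions over a balanced grid of the other factors'
levels (equal weights regardless of observed frequencies) with covariates
at their sample means; ΔCL contrasts are taken against the standard design
(WCB, GAAIN, GAAIN, MNI) and flagged relevant only at |ΔCL| ≥ 3 CL, the
test–retest variability of amyloid PET.  Analyses are stratified by
amyloid positivity, defined per subject by the *harmonized standard
pipeline* CL > 24 (strict inequality).

**Precision model.**  Within- and between-pipeline variability come from
the two-way additive decomposition `CL_ip = μ + subject_i + pipeline_p +
ε_ip`: between-SD is the SD (ddof 1) of the pipeline effects, within-SD the
root mean square of the interaction residuals on (I−1)(J−1) degrees of
freedom, each reported as a 95% half-width (1.96·SD).  A GEE marginal-mean
route for the pipeline effects is available as a cross-check mode.  The
within-pipeline half-width is interpolated linearly between the two
stratum anchors (stratum mean CL, stratum half-width) to give CIs at the
CL 12 and 24 cutoffs; values outside the anchor span extrapolate with a
flag.  The anchor choice (stratum mean CLs) is an assumption of this
implementation.  Harmonized-vs-original agreement uses ICC(2,1) — two-way
random effects, absolute agreement, single measurement (computed via
pingouin) — and Bland–Altman statistics oriented harmonized − original.

**Operating characteristics.**  The statistical battery is validated
against its own ground truth: GEE under independence must reproduce OLS
coefficients to 1e-8; a 1-df Wald chi-square equals the squared robust z;
a null within-subject factor at 300 subjects rejects at ≈5% over 500
replicates; injected additive offsets and variance components are
recovered within sampling error.

## Numerical choices

- Degenerate inputs are handled explicitly: constant response → least
  squares with a warning (GEE cannot iterate on zero scale); single-row
  clusters → independence fallback; singular Wald sub-blocks →
  pseudo-inverse with a warning; constant differences → rank/product
  correlations reported as 0 with a degenerate flag; zero-variance ICC
  pairs → 1 with a degenerate flag; missing long-table cells → additive
  imputation with a warning (or strict error).
- 95% intervals use z = 1.959964 throughout.
- p-values are reported as computed doubles; exported tables keep them
  numeric.
- Resampling shortcuts: an identity voxel map skips interpolation, which
  keeps the ideal-condition chains exact to machine precision.

## Problem sizes

The default study conditions are 60 subjects on a 48³ grid (the package's
chosen balance of cohort size against image volume), 32 pipelines, five
calibration levels × two replicates per tracer, and 500 replicates for the
type-I-error simulation.  All sizes are configuration parameters.

## Limitations

- The phantom has no voxelwise texture, no off-target binding, no
  scanner/sinogram physics, no nonuniform resolution; harmonization is
  pure quadrature smoothing.  Passing tests show the *chain and its
  directions* behave correctly, not that effect magnitudes match any real
  cohort.
- GAAIN-style masks are emulated by one-voxel WM dilation of a template
  target, an acknowledged abstraction of the real template ROIs.
- Simulated effect magnitudes (e.g. pons harmonization shifts, atrophy
  target gaps) are larger than typically reported in real data because the
  phantom's compartments are purer and its noise simpler; signs and
  orderings are the validated quantities.
- No longitudinal component: the framework addresses cross-sectional
  variability only.
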