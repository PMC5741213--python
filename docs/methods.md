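# Methods

This note documents the models, defaults and design choices behind the
package, module by module, including what the synthetic data do and do not
emulate.

## Stimulus generation (`stimgen`)

Filtering operates on the 2-D discrete Fourier transform of a luminance
image in [0, 1]. The radial frequency of coefficient (u, v) — signed
integer cycle counts per axis — is √((u/H°)² + (v/W°)²) in cycles per
degree, computed per axis so mildly anisotropic pixels are handled
correctly. The Butterworth gain (order n, cutoff f_c) multiplies the
complex coefficients; since the gain is real and non-negative, the
amplitude spectrum is attenuated while the phase spectrum is exactly
preserved, and no amplitude can grow (gain ≤ 1; values are clipped at 1 to
absorb float round-off of order 1e-16). The high-pass gain is a true
Butterworth form 1/√(1+(f_c/f)^(2n)) with gain(0) = 0, not 1 − low-pass;
the complementary "1 − gain" variant appears only as a linearity check in
the tests. Low-pass passes DC unchanged; high-pass removes it; the
subsequent normalization restores the luminance match.

Joint contrast/luminance normalization z-scores each image independently
and then applies one shared affine map sending the pooled minimum to 0 and
the pooled maximum to 1. Equal means and SDs across the set follow by
construction; the map is a fixed point on already-normalized sets. Images
with zero variance are rejected rather than silently passed through.

Defaults: 22.7° × 17° field of view; LSF cutoff 0.75 cpd (17 cycles per
image at that field width, by round-half-up conversion), HSF cutoff 6 cpd
(136 cpi), order 2. The default raster is 800 × 600 px (≈35 px/°); any
raster works as long as the band stays below Nyquist. HSF contrast
polarity is made "dark edges on light background" deterministically: the
signed high-pass image is negated whenever its skewness is positive, so
the heavy tail of the edge distribution always maps to the dark end after
normalization.

Noise stimuli impose a band-pass Butterworth amplitude on the phase
spectrum of seeded white noise (which has the conjugate symmetry of a real
image), then rescale to a target mean and SD so noise and scene stimuli are
luminance- and contrast-matched. The band spans one octave
(center·2^(±1/2)) by default. The band-edge roll-off uses order-4
Butterworth edges: on the default grid this concentrates ≥ 95% of the
non-DC spectral energy within one octave of the center, whereas order-2
edges leak ~30–40% outside, which would defeat the purpose of narrowly
defined bands. The edge order is configurable.

One internal inconsistency of the conventional cpi listing is resolved in
favor of cycles per degree: 1.5 cpd at a 22.7° field is 34 cpi (not 24),
and `cpd_to_cpi` returns 34.

## Experiment design (`expdesign`)

Sixteen conditions: 4 scene categories (beach, forest, highway, city) ×
FS/LSF/HSF, plus 4 noise bands. Each run is an independent seeded
permutation of the 16 conditions; blocks last 8 s and are followed by 12 s
fixation. A 10 s lead-in fixation reconciles 16 × 20 s = 320 s with the
~330 s run length (165 volumes at TR = 2 s); whether real runs start with
fixation or a block is an assumption, and the lead-in is configurable.

The HRF is the standard double-gamma difference (peak delay 6 s, undershoot
delay 16 s, unit dispersions, undershoot ratio 1/6, 32 s support),
normalized to unit peak; it peaks near 5 s and starts at exactly 0.
Condition regressors are 8 s boxcars — the 200 ms inter-stimulus gaps
within a block are ignored, modeling the full presentation period —
convolved at 0.1 s resolution and sampled at volume onsets. Note that the
canonical undershoot leaves ~1–2% of the regressor peak 30 s after a block
onset; the regressor is exactly zero only once the kernel has fully passed
(onset + 40 s).

Drift regressors are discrete orthonormal polynomials (QR of the
Vandermonde basis) per run, order 2 by default; discrete orthonormality is
exact, unlike sampled Legendre polynomials. Motion columns, when supplied,
are appended unchanged.

## Synthetic BOLD (`synthbold`)

Per ROI, each condition receives an independent unit-norm Gaussian voxel
pattern; one additional shared "frequency axis" pattern is added with
positive sign for high-frequency conditions (HSF scenes, 3/6 cpd noise) and
negative sign for low (LSF scenes, 0.75/1.5 cpd noise), so binary frequency
decoding can be tuned independently of category decoding. A per-condition
uniform amplitude offset drives univariate contrasts. Effect sizes resolve
from scalars or mappings keyed by (ROI, condition), condition label,
FS/LSF/HSF, low/high class, or ROI name — most specific key wins; they are
in the units of `noise_sd` (default 1), so they read as signal-to-noise
amplitudes.

The voxel time series is baseline (100) + Σ_conditions regressor × weight +
AR(1) Gaussian noise (lag-1 coefficient 0.3 by default, stationary from the
first volume) + random per-voxel quadratic drift + a 6-parameter random-walk
motion time course coupled to random voxel loadings. The motion parameters
are attached to each run, as motion estimates would be for real data.
Everything is reproducible bit-for-bit from the seed.

What this emulates: the dimensionality, block structure, autocorrelated
noise, drift and motion nuisance, and controllable multivariate and
univariate signal of a 10-subject, 8-run experiment. What it does not:
hemodynamic nonlinearity, physiological noise spectra, spatial noise
correlations, inter-subject anatomical variability, or image-derived
pattern structure (patterns are random directions, because the claims under
test concern decodability, not visual feature coding). Passing tests
therefore validate the analysis machinery, not claims about real cortex.

The anterior/posterior ROI split stably sorts voxels along the designated
axis and splits at the median position; odd counts favor the posterior
half, and fully degenerate coordinates fall back to stable input order.

## Preprocessing and GLM (`preproc_glm`)

Percent signal change is computed per run and voxel against the mean of the
late fixation baseline: the last 6 s (3 volumes) of each 12 s fixation
period, excluding the lead-in, to avoid hemodynamic bleed-over from the
preceding block. Zero baselines raise an error naming the offending voxels.

The GLM is ordinary least squares per voxel via a QR factorization shared
across voxels; rank deficiency is detected from the R diagonal and reported
with the collinear column names. The multivariate GLM contains only
nuisance regressors (drift + motion), so task signal survives into the
residuals by design; residualizing residuals again is a no-op.

Pattern extraction takes, for each block, the 4 residual volumes starting
at onset + 4 s (a time t belongs to volume ⌊t/TR⌋, 0-based) and averages
them: 8 runs × 16 blocks × 4 acquisitions = 512 volumes → 128 samples per
subject. Averaging raw residual volumes is assumed (no per-volume
renormalization before averaging).

Contrast t-maps use the standard c'β̂ / √(σ̂² c'(X'X)⁻¹c) with per-voxel
residual variance; ROI definition thresholds the t-map, labels 6-connected
components, drops clusters below a minimum size, and returns the largest —
a desk-scale stand-in for cluster-corrected localizer inference. An empty
result is returned as an empty ROI, not an exception. Gaussian smoothing
uses σ = FWHM/(2√(2 ln 2)) per axis in voxel units with reflective
boundaries (sum-conserving); 4 mm FWHM is conventional for univariate maps
and 2 mm for multivariate, with smoothing left out of the synthetic
pipeline default because synthetic patterns carry no spatial structure.

## Decoding (`decode`)

The decoder is a linear SVM (libsvm via scikit-learn) at C = 5·10⁻⁶. The
multiclass scheme is one-vs-one majority voting over the pairwise decision
values, with ties broken by the largest summed signed decision value and
then by the lowest class index — the scheme used by the underlying SVM
library is a known degree of freedom of this analysis, so the vote is
implemented explicitly and deterministically here. No per-fold feature
scaling is applied: patterns enter exactly as produced upstream. Folds
leave out one run at a time; a class missing from any training fold is an
error naming the fold and class, and train/test run disjointness is
asserted on every fold.

At C = 5·10⁻⁶ the solution is heavily regularized: on separable data its
weight vector approaches the class-centroid difference rather than the
hard-margin solution, which is the intended behavior (large effective
margins, robust out-of-sample generalization with ≤ 28 training samples in
hundreds of dimensions). Margin-maximization checks against an exhaustive
hyperplane search are therefore run in the hard-margin regime (large C),
where "maximum-margin classifier" is well defined; for symmetric class
configurations the low-C and hard-margin boundaries coincide (midpoint
rule), which is checked at the default C.

Frequency decoding for noise stimuli defaults to relabeling the four band
samples per run as low (0.75, 1.5 cpd) vs high (3, 6 cpd), keeping 4
samples per run; `average_within_class=True` instead averages the two
bands of each class within each run first (2 samples per run), an
alternative reading of the conventional procedure. The default keeps every
sample because discarding within-class variation changes fold sizes and
tends to inflate accuracy on small designs.

## Statistics (`stats`)

Accuracy-vs-chance tests are planned one-tailed one-sample t-tests (upper
tail, "greater than chance"); between-condition tests are planned
two-tailed paired t-tests. Cohen's d is (mean − null)/SD, and for paired
comparisons the SD of the differences (the d variant is otherwise
unspecified in this literature; the paired-differences form matches the
test actually performed). No multiple-testing correction is applied to
planned tests; Holm correction is available for exploratory batches.
Degenerate inputs (zero variance, mismatched lengths, n < 2) raise rather
than returning NaN; the pipeline converts zero-variance group accuracies
(all subjects at ceiling) to NaN rows explicitly.

## Pipeline (`pipeline`)

Child seeds are SHA-256 hashes of (master seed, stage, subject), reduced
modulo 2³¹, giving reproducibility with independence across stages. The
default experiment uses 10 subjects, 100 voxels per ROI and box-shaped
ROIs (PPA — generated as separate posterior/anterior halves so their
effects can differ, and analyzed as pPPA, aPPA and their union — plus RSC,
OPA, LOC). Problem sizes were chosen so the full default experiment
completes in seconds on a single core while keeping ≥ 100 test patterns
per accuracy estimate; all sizes scale up through the config. Results are
written as per-subject events.tsv and decoding JSON plus group-level TSV
tables; stimulus generation from photographs is a separate entry point
(`sfscene stimgen`) since the synthetic experiment embeds abstract
patterns rather than image-derived responses.

## Known limitations

- Synthetic patterns are spatially unstructured; spatial smoothing and
  searchlight-style analyses cannot be meaningfully evaluated on them.
- The AR(1) + white noise model understates low-frequency physiological
  noise; drift regressors absorb most of what matters at block timescales.
- The binomial bands used in calibration checks ignore the weak
  across-fold dependence of LORO accuracies, so group means a little
  outside the band can occur at some seeds without indicating bias.
- The SVM at very low C is not a margin maximizer; see the decoding section
  for how oracle comparisons are scoped.
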