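# Methods

This note records the models, parameter defaults and numerical choices
behind `ocuflow`, and what the synthetic benchmarks do and do not
demonstrate about real conjunctival video.

## Scene model (synthetic videos)

A vessel is a dark tube of constant diameter D along a cubic spline
through user waypoints, on a bright sclera (background intensity 200 of
an 8-bit-like range).  Rasterisation is by distance-to-spline: a pixel's
vessel coverage ramps linearly over the last pixel of the radius
(anti-aliasing), and the ground-truth mask keeps pixels with at least 75%
coverage.  That contour was chosen deliberately: the diameter estimator
is defined as twice the Euclidean distance transform (EDT) at the
centreline, and the EDT of the 75%-coverage mask reproduces D to within
one pixel, whereas the half-coverage contour would bias it by about +2 px
on integer-centred tubes.

Red-cell aggregates ("plugs") are periodic Gaussian darkenings (length
40 µm, spacing 130 µm, σ = length/4) advecting along the centreline at a
constant axial speed in arc-length parameterisation, so the ground-truth
velocity is well defined on curved vessels.  Tube darkness between plugs
is 55% of the full vessel contrast (default contrast 0.5).

The scene also contains a static low-contrast speckle (SD 3 intensity
units, correlation length ~3 px) standing in for scleral texture.  It is
not photorealism: without any static background structure, rigid
registration of a straight vessel is ill-posed along the vessel axis and
the moving plugs can bias the correlation peak, which does not happen on
real sclera.

Acquisition effects, applied in order: per-frame Gaussian focal blur
(default σ 0.8 px), rigid jitter (Gaussian, SD 1 px, integer-rounded by
default so that registration recovery is exactly checkable; subpixel
optional), and sensor noise (Gaussian, SD 4 ≈ 4% of the vessel contrast
depth).  Defaults follow the acquisition protocol: 60 frames/s, 10 s
(600 frames), vessels 15–30 µm, speeds 0.3–0.7 mm/s.  Tests and the
acceptance script use 40–100-frame clips — the estimators converge within
~1 s of footage, and the shorter clips keep the whole suite desk-scale;
this is a problem-size choice, not a change of conditions.

Not modelled (and therefore not demonstrated by passing tests): the
pulse-cycle velocity waveform, blinks and saccade interruptions,
specular reflections, eyelash occlusion, vessel networks with crossings,
and diameter variation along a vessel.

## Cohort model

Each continuous variable is drawn per group from a normal or lognormal
family whose arithmetic mean and SD equal the published group summaries
(the lognormal is moment-matched on the natural scale).  Markers whose
SD exceeds their mean (NT-proBNP, CRP, H-FABP, IL-6, ADMA) are lognormal;
the rest normal.  Binary history variables are Bernoulli at the published
proportions.  Between-variable dependence uses a Gaussian copula with a
single exchangeable latent correlation, default 0.0 — no correlation
structure is published, so none is asserted; the parameter is exposed for
sensitivity analyses.  Values below a variable's assay LOD are flagged;
the generated value is retained so censoring can be recounted exactly.

Because the simulator draws variables (conditionally) independently at
the published marginal moments, the *joint* behaviour of the screening
models — which variables enter, the achieved AUROC — reflects those
marginals only.  A synthetic AUROC is a demonstration of the machinery,
not a reproduction of the clinical result.

## Registration

The sharpest frame — maximum variance of the Laplacian response, a
standard focus measure that is monotone in the simulator's Gaussian
defocus — is the reference; ties break to the lowest index.  All frames
are aligned by translation only (slit-lamp micro-saccade motion is
predominantly translational) using phase cross-correlation with spectral
whitening.  Whitening matters: plain correlation let the advecting plugs
pull the peak by up to 3 px whenever their phase nearly matched the
reference.  Shifts are integer-pixel by default, recovering the
simulator's integer jitter exactly; `subpixel=True` upsamples the
correlation peak tenfold.  Out-of-view pixels are filled with the frame's
median intensity.

## Vessel geometry

Segmentation: large-kernel Gaussian background flattening (σ 25 px),
multi-scale Sato tubularity filtering of the darkness image, and a
threshold at 30% of the robust (95th-percentile) vessel darkness, keeping
only darkness components supported by the tubularity response
(morphological reconstruction), then small-object removal and closing.
The threshold fraction places the boundary near the three-quarter-
coverage contour of the tube, matching the EDT convention above.  A
constant frame yields an empty mask, not an error.

Centrelines: iterative thinning; side spurs shorter than 10 px are pruned
before branches are split at junction pixels; each branch is traced
end-to-end and lightly smoothed (7-point moving average) — the raw
8-connected chain inflates arc length by several percent, which would
propagate directly into velocity.  Per-segment quality is the fraction of
centreline with local darkness above a floor (10 intensity units);
segments with quality < 0.5 or length < 50 µm are excluded from patient
aggregation.  Both thresholds are configurable.

Diameter: D(point) = 2 × EDT × µm/px at the nearest pixel to each
centreline point; the segment diameter is the mean over points.  This is
exactly the brute-force nearest-background-pixel distance (verified
against that oracle on randomised masks).

## Velocimetry

The spatio-temporal image (STI) samples each registered frame by
bilinear interpolation at 1-px arc-length steps along the centreline.
Two background terms are removed: the temporal mean per arc-length
position (the static tube profile and scleral texture — left in place,
static structure correlates at zero lag and biases any slope estimator
toward stillness), then each row's mean (illumination drift).

Axial velocity: each row is transformed with a Mexican-hat continuous
wavelet (matched to blob-like dark aggregates), scales spanning 0.5–2×
the plug length (default 20–80 µm, 8 geometric steps).  The per-row
modulus-maximum ridge is refined to sub-sample precision by a parabolic
fit and tracked over rows; per-interval displacements larger than 25% of
the STI length (plug hand-overs) are discarded, and Va is the median of
the rest, reported as a magnitude (direction is not reported).  A track
is declared *indeterminate* — distinct from a confident zero — when fewer
than half the intervals associate, or when the streak SNR (maximum
allowed jump over the robust dispersion of the valid displacements, with
a +1-sample quantisation floor) falls below 5: an incoherent, noise-driven
ridge wanders with near-uniform dispersion and fails this floor, while
both moving and stationary coherent patterns pass.

An independent oracle (exhaustive integer-lag normalised cross-
correlation of consecutive rows, median lag) is used in tests only; the
wavelet estimator agrees with it within a few percent on simulated
vessels and both recover the ground truth within 10% at default noise.

Conversions: Vs = Va / k with k = 1.42 by default, inferred from the
published paired Va/Vs group means (0.54/0.38 and 0.50/0.35); a constant
factor is an assumption — a diameter-dependent profile factor is not
implemented.  Q = Vs·πD²/4 with Vs in µm/s and 1 pl = 10³ µm³;
WSR = 8·Vs/D in s⁻¹.  Emitted haemodynamics records enforce these
identities at construction time.

## Biomarker preparation

Below-LOD results are imputed as 90% of the LOD and flagged; the rule is
idempotent and never touches detectable values.  The packaged LOD table
carries all twenty published assay limits.  Default log₁₀ variables are
NT-proBNP, adiponectin, H-FABP and WSR (the ones modelled on the log
scale); any other variable is transformed only when the Shapiro–Wilk gate
(p > 0.05, n between 3 and 5000) fails.  Patient pooling gives every
included segment equal weight across the up-to-four videos of both eyes
("segment" weighting); per-video-mean weighting is available because the
published description ("overall mean of each parameter per patient") is
ambiguous between the two.  Zero included segments yields an explicit
"ocular missing" outcome.

## Screening statistics

Group comparisons: independent t-test when both groups pass the
Shapiro–Wilk gate, otherwise Mann–Whitney U; for the rank branch both the
median/IQR and the mean-rank summaries are reported, since which of the
two the reader should quote depends on whether the group distributions
have similar shape — a judgement left to the caller.  Binary variables
use the Pearson χ² on the 2×2 table *without* continuity correction
(df = 1); the uncorrected statistic is what reproduces the published
gender value (1.91, where Yates would give 1.40).

Logistic regression: maximum likelihood by iteratively reweighted least
squares (Newton steps), convergence when the log-likelihood changes by
< 1e-8 or after 50 iterations; standard errors from the observed
information; Wald = (β/SE)² against χ²₁.  Rank-deficient designs are
rejected naming the collinear columns (QR with pivoting); perfect
separation is detected via a diverging linear predictor (|Xβ| > 30) and
flagged rather than silently returned.

Stepwise selection: forward entry by the Rao score test evaluated at the
current MLE, Bonferroni-adjusted over the candidates examined at that
step so the family-wise entry rate stays at the nominal p_enter = 0.05;
after each entry, backward Wald elimination removes any included variable
with p > p_remove = 0.10; iterated to a fixed point.  Without the
adjustment, a five-candidate global null would admit a spurious variable
in ~23% of datasets; with it, the intercept-only model is returned in
well over 90% of null replicates while a 1-SD effect at n = 2000 is still
selected essentially always.  The full enter/remove trace is recorded and
replaying it reproduces the final model bit for bit.

Fit quality: Nagelkerke R² (Cox–Snell rescaled by its maximum);
Hosmer–Lemeshow over deciles of fitted risk with ties kept together
(df = groups − 2; groups with degenerate expected counts are merged into
a neighbour and the merge recorded).  ROC: thresholds at every distinct
score, trapezoidal AUROC (equal to the Mann–Whitney concordance
probability, ties counted half), operating point at the fitted-probability
cut 0.5 by default — whether a published sensitivity/specificity pair
sits at 0.5 or at an ROC-optimal cut is generally not stated, so the
Youden-optimal point is reported alongside.  The multi-model report ranks
variable sets by AUROC with sens/spec/PPV/NPV percentages at the cut.
In-sample nesting is guaranteed for the log-likelihood, not for the
AUROC, which can dip marginally when a weak variable enters a model.

## Pipeline and reproducibility

`run_pipeline` fans a single seed out to per-stage child seeds through
`numpy.random.SeedSequence`; the manifest records config, seed, package
version and per-stage wall time and row counts, and a rerun with the same
inputs reproduces every CSV byte for byte.  Any stage failure halts the
run with partial outputs retained.  Videos are written as multi-page TIFF
with a JSON calibration sidecar; all tables are CSV.

## Known limitations

- Velocity is aliased above ~(25% of segment length) per frame; very fast
  flow in short segments returns indeterminate rather than wrong values.
- The k = 1.42 profile factor is a single constant; no diameter or
  haematocrit dependence.
- Arteries and veins are not differentiated; all segments pool equally
  into the patient mean.
- The synthetic cohort cannot validate the clinical discriminative
  performance of any marker combination, only the correctness and
  calibration of the statistical machinery.
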