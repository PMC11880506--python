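# Methods

This note documents the models, parameters, and numerical choices behind
`facedecode`, and what the synthetic test bed does and does not establish
about real recordings.

## Experimental design encoded

The stimulus catalogue is the Cartesian product of 8 identities (4 per
sex) and 4 expressions (happy, angry, sad, neutral): 32 unique images. A
session presents each image 12 times in a 2AFC expression task (384
trials); each image's veridical expression is paired with each of the 3
possible foil expressions 4 times, and within every (image, foil) pair the
correct-choice key side is split evenly. Because 12/3 = 4 is even the
split is exact; for repetition counts whose per-foil count is odd the key
side alternates deterministically within the pair, so counts never differ
by more than one. Incorrectly answered trials are re-inserted at a
uniformly random later position until every image has its full count of
correct trials; behavioral summaries use first presentations only.
Reaction times are stored in seconds; report tables render milliseconds.
The six pairwise RT contrasts use Wilcoxon signed-rank tests on
per-participant median RTs, p-values uncorrected.

## Synthetic cohort generator

Each trial's signal is

```
x(trial, channel, t) = Σ_effects  a · p_level(channel) · w(channel) · hann(t; onset, duration)
                       + smoothed Gaussian noise
```

where `p_level` is a unit-RMS Gaussian channel pattern drawn per level of
the effect's attribute (sex / identity / expression / image), `w` an
optional topography weight, and `a` the amplitude in units of the noise
standard deviation. Effects marked *shared* draw patterns once from the
master seed, so every participant carries the same code — exactly the
premise that leave-one-participant-out decoding tests; non-shared effects
redraw patterns per participant and are invisible to cross-participant
classifiers (verified by test).

Noise is Gaussian, temporally smoothed with a Gaussian kernel (σ = 20 ms
by default) and rescaled to unit variance: enough autocorrelation to make
calibration tests honest about EEG-like smoothness without a 1/f model,
spatial covariance, or artifact simulation. The generator therefore shows
that the *analysis chain* is correct and calibrated; it does not show
robustness to real-world artifacts, volume conduction structure, or
non-stationarity.

Defaults mirror the study geometry: 24 participants, 64 channels on the
standard BioSemi-64 montage, 200 Hz, epochs on the half-open grid
[−200 ms, 1200 ms) — exactly 280 samples, matching the RDM time dimension
(a closed interval would give 281) — and 12 repetitions. Synthetic
stimulus rasters (identity/sex/expression templates + pixel noise, with
configurable weights) and identity-clustered 128-dimensional embedding
vectors stand in for face photographs and face-recognition descriptors
when building image-property model RDMs; they are synthetic stand-ins, not
derived from any image set.

## Preprocessing

Order: band-pass filter → baseline correction → downsample → pseudo-trial
binning. Filtering is a zero-phase 4th-order Butterworth band-pass
(0.1–40 Hz), applied forward-backward; the 0.1 Hz edge has a
seconds-long impulse response, so the filter pads by 5/low seconds and is
meant for continuous-length data (the synthetic generator produces
band-limited signals, so the pipeline leaves filtering off by default).
Baseline is the mean over [−200, 0) ms. Downsampling uses polyphase
resampling with anti-aliasing. Pseudo-trials average random bins of 3
same-image trials (a random partition per image per participant, seeded);
incomplete bins are dropped rather than averaged short, keeping
pseudo-trial noise variance homogeneous at ≈1/3 of trial noise.

## Decoding

The classifier is a linear discriminant with the least-squares solver and
Ledoit–Wolf covariance shrinkage — at searchlight scale channels rival
trials per class, so unshrunk covariance is ill-conditioned. The package
ships its own implementation of the identical decision rule (standardize
features per class, Ledoit–Wolf shrink, pool by class priors,
`argmax_k x·Σ⁻¹μ_k − ½μ_k·Σ⁻¹μ_k + log π_k`) because per-call validation
overhead in general-purpose estimators dominates at the ~10⁵ fits of a
searchlight; prediction equivalence with scikit-learn's
`LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")` is asserted
in the test suite, and the scikit-learn estimator remains available via
`ClassifierConfig(use_sklearn=True)`. Features are raw channel amplitudes
at single timepoints.

Fold structure: identity decoding holds out one expression (4 folds per
held-out participant). Sex/emotion/pair decoding holds out one identity;
since removing one identity leaves 3 of its sex and 4 of the other, one
*opposite-sex* identity is additionally excluded so training stays
balanced at 3 male / 3 female — the excluded identity rotates over the 4
candidates and all rotations are averaged (32 folds per participant).
Without this balance, class priors systematically bias the classifier
against the held-out identity's sex (noise-only sex decoding drops to
~0.10 instead of 0.5), which is why the balanced rule is treated as part
of the design. Cross-classification restricts training to one condition
and testing to the other, runs both directions, and averages them within
participant; for identity schemes the condition split replaces the
expression holdout.

Searchlight adjacency comes from Delaunay triangulation of the
azimuthal-equidistant-projected electrode positions (first-order
neighbors; a distance threshold is available). The six regions of
interest split the montage by the sign of the left–right coordinate
(midline channels join both sides) and terciles of the
anterior–posterior coordinate; the lists are derived from the montage by
this rule.

## RSA

Neural RDM cells are LOSO pairwise decoding accuracies, computed per
held-out participant (fold-resolved) so group statistics receive one RDM
series per participant; the diagonal is masked. "Maximum
cross-correlation" image similarity is implemented as the maximum over
all integer 2-D translations of the Pearson correlation of the
overlapping region (images z-scored first), computed exactly via FFT sum
tables and verified against an exhaustive-shift loop; shifts overlapping
less than half the pixels are excluded, since one- and two-pixel overlaps
give degenerate correlations of ±1. Dissimilarity is 1 − max
correlation; a literal Euclidean-distance-at-best-shift variant is
available behind a flag. Partial Spearman correlations rank-transform all
vectors (average ranks at ties), regress covariate ranks plus an
intercept out of both sides, and correlate the residuals — equal to the
recursive partial-correlation formula for a single covariate (tested).
Residuals that are numerically zero (self-residualization) return ρ = 0.

A caution on interpretation: partialling a covariate out of a neural
structure that genuinely contains it removes variance from the neural
side too, so the correlation of an *independent* model can rise. The
meaningful contrast is directional — an image-correlated identity
component is attenuated; an image-independent expression component is
not — and that is what the tests assert.

## Group statistics

Smoothing: centered 35 ms moving average (7 samples at 200 Hz), shrinking
at the edges; smoothing precedes testing by default and is config-visible.
Cluster permutation test: one-sample *t* per point on (value − chance);
the cluster-forming threshold is the two-tailed p = 0.05 *t* quantile at
n−1 df; positive and negative clusters form separately (temporal
contiguity, plus channel adjacency for channel × time input) and each
cluster's summed-*t* mass is compared against the permutation
distribution of the maximum absolute mass under participant-wise sign
flips — (b+1)/(m+1) for sampled permutations, exact proportions when the
2ⁿ flip space is enumerated (automatic for small n). The exhaustive null
contains only 2ⁿ⁻¹ distinct values (a global sign flip preserves |t|), so
achievable family-wise rates are quantized: ~0.031 at n = 6, ~0.047 at
n = 8 — the calibration suite therefore uses 8 participants.

Interval-null Bayes factor: both hypotheses are truncations of the same
non-directional Cauchy(0, 0.707) effect-size prior — outside vs. inside
|δ| ≤ 0.5 — and their marginal likelihoods integrate the noncentral-*t*
density of the observed statistic over the prior, computed in the prior's
CDF domain (where the Cauchy weight is uniform) with adaptive quadrature;
a dense-grid quadrature oracle pins the values in tests. Statistics are
saturated at |t| = 50 (zero-variance samples give t = ∞; the BF is
monotone in |t| and far beyond any threshold there). The point-null JZS
variant is exposed for comparison. Cohen's d is mean/sd of
(value − chance); zero-variance points yield flagged infinities.

Onset/peak: onset is the first run of at least `min_run` samples with
BF > 10, peak the first local BF maximum within that run. Because the
interval-null BF is non-directional, only above-chance evidence counts
toward onsets by default (below-chance dips occur: LOSO folds share
training data, so participants are not independent and momentary |t|
values inflate). The default `min_run` is 1; the parameter-recovery
protocol debounces with one smoothing window (7 samples) for the same
reason.

## Validation protocols and problem sizes

`facedecode.protocols` fixes the study-shaped validation runs: chance
calibration on a signal-free cohort (6 participants × 64 channels × 50
timepoints; identity/sex/emotion grand means land on 0.125/0.5/0.25);
family-wise error of the cluster test over 500 null cohorts (8
participants, exhaustive flips; rate within the binomial band around
0.05); onset recovery (8 participants × 16 channels × 80 timepoints per
attribute, effects of amplitude 1.5 at 50/90/130 ms, recovered within one
smoothing window and in the planted order); and the partial-correlation
attenuation contrast on planted RDM compositions. Onset recovery plants
one effect per cohort: attribute hierarchies overlap (any pattern
separating the sexes also separates identities across sex), so jointly
planted effects would confound threshold-crossing onsets. These reduced
sizes preserve the full analysis logic while keeping each protocol in the
minutes range on one CPU.

## Known limitations

- No forward-model (leadfield) simulation, artifact simulation, 1/f noise,
  or spatial noise covariance; calibration results speak to the analysis
  chain, not to robustness against those properties of real data.
- No re-referencing, ICA, artifact rejection, temporal generalization
  matrices, nonlinear classifiers, cross-validated RDM distances, noise
  ceilings, or FDR across analyses.
- Recording import is limited to the package's HDF5 container; reading
  vendor formats (e.g. BioSemi BDF) should go through MNE-Python upstream
  of `EpochsCollection`.
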