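# Methods

`facedecode` re-implements, as a tested and reusable pipeline, the
analysis chain of a time-resolved EEG study of face perception: rapid
serial presentation of hundreds of naturalistic face images, behavioral
ratings of two facial attributes (emotional valence and perceived
masculinity), multivariate decoding of the evoked EEG, representational
similarity analysis (RSA) against the behavioral ratings, and
Bayes-factor time-series inference with latency estimation.  Because
every downstream stage must be testable without access to a recorded
dataset, the package ships a first-class synthetic-data generator with
retrievable ground truth.

## The emulated study design

The default configuration mirrors the emulated experiment throughout:

| parameter | default | meaning |
|---|---|---|
| stimuli | 900 (840 human faces, 60 non-face images) | condition set |
| valence raters | 60 × 300 ratings | 9-point scale, 1 = very negative |
| sex raters | 72 × 300 ratings | 9-point scale, 1 = very feminine |
| presentation | 72 sequences × 150 trials | 10,800 trials per subject |
| blocks | 12 blocks of 6 sequences | each block shows every stimulus once |
| EEG | 64 channels, 256 Hz | epochs −100…1000 ms (282 samples) |
| extreme classes | k = 200 lowest / highest rated | class-decoding conditions |
| JZS prior scale | 0.707 | Cauchy prior on effect size |
| null intervals | [0, 0.5] one-sided; [−0.5, 0.5] two-sided | accuracy / correlation tests |
| decision rule | BF > 10 (alt) or < 1/10 (null), ≥ 2 consecutive samples | contiguity filter |

`SimConfig.desk_scale()` provides a reduced design (20 stimuli, 4
subjects, 16 channels, 12 blocks of 2 × 10 trials, epochs −100…400 ms)
that preserves every structural constraint of the full design while
running in seconds; the test suite and the acceptance script use sizes
of this order so a complete run stays within minutes on one CPU.

## Synthetic data model

**Latent attributes.**  Each stimulus carries a latent (valence, sex)
pair drawn from a standard bivariate normal with correlation −0.1 — a
small negative association, mirroring the empirical tendency for more
masculine-looking faces to be rated more negative.

**Ratings.**  Each rater scores a uniform random subset of stimuli
(rejection-resampled until every stimulus is rated at least once; the
balancing scheme across raters is deliberately unspecified).  A rating
is `round(clip(5 + 1.8·latent + ε, 1, 9))` with ε ~ N(0, σ²),
σ = 1 rating point by default and rounding half-away-from-zero.  The
affine map centers the scale at its midpoint 5 and the slope 1.8 lets
±2 SD of the latent span the 9-point scale.  This deliberately models
no rater psychology (anchoring, sequence effects, individual biases).

**Images.**  8-bit grayscale squares (64 px by default — large enough
for a meaningful radial spectrum, small enough to generate hundreds in
milliseconds) with per-class mean luminance, white-noise texture SD,
and an optional additive low-spatial-frequency sinusoid, so the
image-statistics control has controllable group differences to detect.

**Epochs.**  A trial's sample at channel c and time t is

```
x = noise + a_img · P_img[s, c] · g_img(t) + Σ_attr a_attr · z_attr[s] · p_attr[c] · g_attr(t)
```

* `noise`: iid Gaussian mixed across channels by a seeded random matrix
  `(1−m)·I + m·G/√C` (m = 0.5); spatially correlated noise keeps the
  shrinkage-LDA problem realistic — white noise would make it too easy.
* `P_img`: a fixed random pattern per stimulus (image specificity, the
  signal the pairwise decoder detects).
* `z_attr`: the stimulus's standardized latent attribute.  Scaling the
  class pattern by the latent value, rather than by a binary class
  indicator, serves both recovery analyses at once: the extreme classes
  are separable (class decoding) *and* pairwise neural dissimilarity
  grows with the rating gap, which is exactly the structure RSA must
  recover.
* temporal gates `g`: zero before onset, half-Gaussian rise
  (SD = (peak−onset)/3, so the gate is ≈1 % of maximum at onset) to 1
  at the peak, exponential decay afterwards (τ = 150 ms).  This
  produces distinct, orderable onset and peak — the two quantities the
  inference stage estimates.  Pre-stimulus samples contain noise only.

Structural randomness (mixing matrix, stimulus patterns, class
patterns) depends only on the study seed and is shared across subjects;
per-subject noise uses the subject seed.  Identical seeds give
bit-identical output.

**What the generator does not emulate** — and hence what passing tests
do not show about recorded EEG: eye movements, blinks, alpha and other
oscillatory background, channel drift/impedance changes, inter-subject
variability in effect topography or latency (all subjects share the
injected patterns and timing), overlapping responses from the rapid
stimulation, and any veridical face-image structure in the synthetic
stimuli.  Recovery results demonstrate that the pipeline is correct and
calibrated, not that any particular effect exists in real data.

## Preprocessing

Fixed order: band-pass filter → bad-channel detection/interpolation →
average re-reference → downsample (1024 → 256 Hz) → epoch → per-epoch
linear detrend → crop (−100…1000 ms).  No notch filter.

* **Filtering** is zero-phase (forward–backward) IIR.  The two corners
  are separate stages: a 2nd-order 0.1 Hz high-pass run with
  transient-minimizing initial conditions (at a corner this close to DC
  the default odd-extension padding leaves multi-second edge
  transients; the signal is demeaned first), then a 4th-order 100 Hz
  Butterworth low-pass in second-order sections with generous padding.
* **Bad channels** use a probability criterion: a Gaussian-kernel
  estimate of the pooled amplitude distribution scores every channel's
  samples; the per-channel mean negative log-likelihood is turned into
  a robust z-score (median / 1.4826·MAD across channels) and channels
  beyond 5 are flagged.  A plain SD-based z-score is mathematically
  bounded by (C−1)/√C (≈2.5 at the 8-channel minimum), so the
  documented threshold of 5 could never fire; the robust scale makes
  the criterion attainable at any channel count.  Pooling subsamples by
  stride, not at random, so detection is deterministic.
* **Interpolation** replaces a bad channel by the inverse-distance-
  weighted (power 2) average of good channels; simulated recordings use
  a synthetic ring montage.  Spherical-spline interpolation is a
  config-exposed alternative left unimplemented.
* **Downsampling** is polyphase with built-in anti-aliasing; epochs are
  cut on the onset-aligned sample grid (every integer multiple of the
  3.90625 ms period inside the window; −100…1000 ms → 282 samples),
  detrended by least squares over the wide extraction window
  (−533…1066 ms) and then cropped.  Events without full window support
  are dropped with a logged warning.
* A hardware-reference stage (temporary single-channel reference before
  filtering) is unnecessary for synthetic data and is skipped.

## Decoding

The classifier is two-class LDA with a pooled within-class covariance
shrunk analytically toward scaled identity.  The shrinkage intensity is
the closed-form oracle-approximating (OAS) formula, which depends only
on tr(S), tr(S²), the trial count and the channel count — chosen over
cross-validated shrinkage because it vectorizes over timepoints and has
no tuning randomness.  With 64 channels and as few as ~20 training
trials per fold, unregularized LDA would be singular.  Features are the
raw channel amplitudes at a single timepoint (no temporal stacking);
all timepoints of a fold are solved in one vectorized pass.  Ties at
the decision boundary go to class 0 (strict inequality); classes are
balanced by construction so equal priors are used.

* **Pairwise image decoding**: every unordered stimulus pair,
  leave-one-block-out (train 11 blocks, test 1; 12 folds).  The mean
  over pairs indexes image specificity (chance 50 %); the per-pair
  accuracy matrix is retained and doubles as the neural RDM.
* **Class decoding with exemplar generalization**: the k lowest- vs k
  highest-rated stimuli.  Low and high exemplars are paired after a
  seeded shuffle (the pairing rule is otherwise arbitrary); each of the
  k pairs is held out crossed with each block (k × 12 folds), training
  on the other k−1 exemplars per class in the 11 remaining blocks only.
  Above-chance accuracy therefore requires generalization to stimuli
  never seen in training.
* Fold accuracies are averaged (not pooled-prediction accuracy); group
  results are unweighted subject means with the per-subject stack kept
  for inference.

## RSA and noise ceiling

The neural RDM at each timepoint is, by default, the matrix of
cross-validated pairwise decoding accuracies — the pairwise analysis
computes exactly the n(n−1)/2 dissimilarities the RSA needs, so the
default reuses them; 1 − Pearson correlation between per-condition mean
patterns is available as an alternative metric and the choice is
recorded in output metadata.  Behavioral RDMs are absolute differences
of group-mean ratings.  Correspondence is Spearman rank correlation on
condensed vectors, per subject per timepoint, then averaged; a
human-faces-only variant subsets both RDMs before correlating.  The
lower-bound noise ceiling rank-transforms each subject's RDM and
Spearman-correlates it with the mean rank-transformed RDM of the
remaining subjects (leave-one-participant-out), averaged over subjects.
No upper bound is computed.

## Bayes-factor inference

One-sample evidence at each timepoint uses the Jeffreys–Zellner–Siow
setup: Cauchy prior (scale 0.707) on the standardized effect size δ,
marginal likelihood of the observed t-statistic obtained by integrating
the noncentral-t density over the prior.  Interval nulls follow the
truncated-prior reading: H0 carries the renormalized prior on δ inside
[lo, hi], H1 on the admissible complement ([0, ∞) for one-sided tests
of above-chance accuracy, the full line for two-sided correlation
tests); BF10 is the ratio of marginal likelihoods.  A point null
(lo = hi) reduces to the classic JZS t-test Bayes factor, and the
interval form converges to it as the interval shrinks (tested).

Numerics: each integration region is mapped to a finite segment
(tan-substitution with Cauchy-scale parametrization for infinite
tails) and integrated with 120-node Gauss–Legendre quadrature; the
integrand is smooth in δ, and the engine agrees with an independent
adaptive-quadrature oracle to at least four significant figures over a
grid of (t, n).  |t| is capped at 38 — beyond that the noncentral-t
implementation loses convergence and the Bayes factor is already
decisive; zero-variance samples are a documented limit (BF → ∞ when the
mean differs from the null value).  Bayes factors are reported in
natural units.

Decisions require contiguity: BF10 > 10 (or < 1/10) for at least 2
consecutive samples (configurable); isolated spikes stay inconclusive.
Onset latency is the first post-stimulus sample whose decision favors
the alternative; the peak is the post-stimulus argmax of the group
mean.  Confidence intervals are percentile bootstrap over subjects
(default 1,000 resamples, seeded), re-deriving the group mean, the BF
series and both latencies per resample; inside the bootstrap the BF is
evaluated through a monotone log-space interpolant of the exact
quadrature on a fixed t-grid (n is constant across resamples), keeping
the bootstrap orders of magnitude faster with no visible loss at the
decision thresholds.  Resamples in which no sample is flagged are
counted and excluded from the onset CI.  Onset estimation operates on
the group-level series; per-subject reliability is not required.

## Image statistics

Luminance is the mean pixel intensity and contrast the population SD.
Spatial-frequency content: 2-D DFT amplitude spectrum (power optional
via a flag), DC excluded — DC *is* luminance, which is measured
separately — components binned by integer radial frequency, the set of
distinct radii median-split into a low and a high band, and the radial
profile (per-radius mean) averaged within each band.  No windowing is
applied before the transform.  Group comparisons use the
pooled-variance two-sample t-test (df = n₁+n₂−2, two-tailed), the
variant consistent with df = 398 for two groups of 200; zero pooled
variance with equal means yields t = 0, with unequal means an
infinite-t flag.

## Design choices on genuinely open points

* Ties in extreme-class selection break by ascending stimulus id
  (determinism over any statistical consideration).
* Split-half reliability with an odd rater count drops one rater
  uniformly at random per iteration; stimuli unrated within a half are
  excluded pairwise-complete for that iteration.
* Spearman statistics use average ranks for ties and t-approximation
  p-values.
* The pipeline driver applies the epoch-level tail of preprocessing
  (re-reference, detrend, crop) to simulated epochs; the full
  continuous-recording chain is exercised separately, since the
  generator produces epoched data directly.

## Known limitations

* The full 900-stimulus pairwise analysis (404,550 pairs × 282
  timepoints × 40 subjects) is a cluster-scale computation; the package
  is validated at reduced designs that preserve every structural
  constraint, and the engine scales linearly in pairs × folds ×
  timepoints.
* The EEGLAB-dialect probability criterion for bad channels is a
  defensible re-reading, not a re-implementation of the original code.
* Latency CIs assume exchangeable subjects; no hierarchical model.
* The generator's evoked model is rank-1 per attribute with a shared
  topography across subjects — adequate for calibration and recovery
  testing, simpler than real EEG.
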