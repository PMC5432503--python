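# Methods

## Generative model of the synthetic EEG

Every validation in this package runs against synthetic epoched EEG with
a known position-tuned structure. A trial with target position `p`
(1..k) is generated as

    data(t) = A · W_true · c_true(p) · s(t) + ε(t)

* `W_true` (electrodes × position channels): one spatially smooth scalp
  topography per position channel. Each column is a 2-D Gaussian bump
  (width 0.45 in unit-disc coordinates) over the montage whose centre
  sits over posterior scalp contralateral to the stimulus angle and
  slides anterior for upper-field positions — a coarse retinotopic
  gradient. `GroundTruth.topography(angle)` evaluates the bump at any
  angle.
* `c_true(p)`: a wrapped (circular) Gaussian over the k position
  channels, peak 1 at channel `p`, width `true_tuning_width` = 1.2
  channels by default (≈ 54° for the 8-position display). Neighbouring
  positions therefore evoke overlapping topographies, as neighbouring
  retinotopic positions do.
* `s(t)`: a piecewise raised-cosine envelope, zero before
  `signal_onset` (190 ms), unit at `signal_peak` (264 ms), zero after
  `signal_offset` (500 ms). The timing reproduces the empirical shape
  of position-information time courses: a rapid rise shortly before
  200 ms and a peak in the 240–270 ms range.
* `ε`: Gaussian noise, `noise_sd` = 10 µV, white across electrodes and
  samples by default. An optional `noise_mode="correlated"` draws
  spatially correlated noise with an exponential spatial covariance over
  the montage (length scale 0.6), which stress-tests the Haufe
  transformation (whose whole point is to undo noise covariance in
  classifier weights).

Defaults mirror the 8-position circular-display design: positions at
22.5° + 45°·i clockwise from the top of the screen (position 1 upper
right, none on a midline), 96 trials per position (768 total), 27
electrodes, 250 Hz, epochs −100..600 ms. `SimConfig.experiment1()`
configures the 4-position midline design: angles 0/90/180/270
(top/right/bottom/left), 192 trials per position, 23 electrodes, epochs
−200..400 ms, and a tuning width of 0.6 channels so the *angular* width
matches the 8-position default (neighbours are 90° rather than 45°
apart).

### Why amplitude 10 µV: the SNR regime of the delta-basis CTF

A point worth making explicit, because it governs how the forward-model
results must be read. With the delta basis, the estimated weight matrix
`W` converges to the per-class mean topographies, and the noise-free OLS
inversion of held-out class data returns exactly the delta profile
`e_p` — *not* the generative tuning profile. (This is the same identity
as the round-trip invariant `C2 = (WᵀW)⁻¹Wᵀ(Wc) = c`.) The graded,
Gaussian-shaped CTF observed in practice is a finite-noise phenomenon:
estimation noise in `W` acts like a ridge penalty on the inversion, and
because neighbouring columns of `W` are correlated (overlapping
topographies), that penalty spreads response estimates across
neighbouring channels. The empirical CTF width therefore depends on the
single-trial signal-to-noise ratio: very high SNR drives it toward a
delta, very low SNR toward the doubly smoothed overlap profile.

The default amplitude (10 µV peak against 10 µV noise — a clear evoked
response) was chosen, once, so that the estimator operates in the regime
where the fitted circular-Gaussian width of the CTF matches the
generative tuning width (fitted 1.17 ± 0.06 channels across seeds for a
true width of 1.2, well within 15%). This is the regime real recordings
with clearly graded CTFs occupy. Interpreting CTF widths quantitatively
at very different SNRs would require a calibration like this one.

## Preprocessing

* Re-referencing subtracts the mean of named reference channels (e.g.
  both earlobes) per sample.
* High-pass filtering uses a zero-phase Hamming-windowed sinc FIR
  (MNE's `firwin` design). At the canonical drift-removal setting
  (0.1 Hz pass edge, 0.1 Hz transition band, 250 Hz) the filter is 8251
  taps = 33 s long, so it belongs on continuous data; the function
  refuses data shorter than the filter rather than silently truncating.
* Baseline correction subtracts the per-trial/electrode mean over a
  window (−200..−100 ms for the two-display design, −100..0 ms for the
  circular design).
* Downsampling applies an anti-alias FIR low-pass and decimates on a
  grid anchored at the t = 0 sample, so stimulus onset stays on a
  sample.
* The horizontal EOG is the left minus right outer-canthus channel. The
  saccade **step detector** slides a 100 ms window in 50 ms steps over
  0–500 ms and flags a trial when the means of the window's two halves
  differ by more than 25 µV. Two deliberate choices: (1) "amplitude
  fluctuation" is operationalized as the absolute difference of
  half-window means (the standard ERP-lab step function at a
  saccade-scale threshold); (2) window boundaries are placed on the
  *time* axis, because 50 ms is not an integer sample count at 250 Hz
  and sample-grid placement would silently misalign the windows. A
  consequence of half-window means: a step whose onset falls exactly on
  a half-window boundary is measured at full amplitude, but an onset
  midway between boundaries is attenuated by up to 50%, so detection at
  *arbitrary* onset is guaranteed only for steps ≥ 2× threshold.
  Independent-component blink removal is out of scope; a hook accepts
  externally cleaned data and/or a rejection mask, and rejected trials
  are dropped (with an audit column in the trial metadata), never
  zeroed.

## Decoding

LDA uses class means with a pooled covariance estimated with Ledoit–Wolf
automatic shrinkage (scikit-learn `lsqr` solver). Shrinkage is on by
default because 23–27 electrode covariances estimated from ~90% of a few
hundred trials can be ill-conditioned; `shrinkage=None` recovers plain
LDA. Class assignment is the argmax of the discriminant scores with ties
broken toward the lowest class index. Folds are stratified and shuffled
with a seed (shuffling removes acquisition-order information);
per-class accuracy (recall) is averaged first over classes, then folds,
making the aggregate robust to incidental class imbalance in a test
fold and fixing chance at 1/k.

The Haufe activation pattern multiplies the *training-fold* data
covariance with the classifier weight vector; using only training data
keeps the transform independent of the test set. For multi-class
decoders patterns are per class-vs-rest weight row — an extension beyond
the two-class patterns the method was designed around, and flagged as
such. Spatial normalization z-scores a pattern across electrodes using
the population (divide-by-n) standard deviation; the result is invariant
to affine rescaling of the input either way, the convention only fixes
the numeric values.

Display smoothing (32 Hz resample + cubic spline) anchors the resample
grid at the accuracy peak so the peak is a knot and its height is not
diluted; the smoothed series is for plots only and no statistic in the
package consumes it.

## Forward encoding model

Weight estimation and inversion are ordinary least squares via
`numpy.linalg.lstsq` with its default relative rank tolerance;
rank-deficient designs raise (naming missing classes) rather than
silently pseudo-inverting, and a rank-deficient weight matrix reports
its condition number. The canonical CTF aligns each condition's mean
channel-response vector to centre channel 4 by circular shift and
averages across conditions; the display variant repeats the most distant
channel to make plotted profiles symmetric. Alignment conserves the
channel sum exactly.

Reconstruction of never-presented positions:

1. The group CTF is **line-symmetrized** — averaged with its mirror
   image about the centre channel. The mirror axis through the aligned
   centre is the only symmetry consistent with a profile that depends
   on positional distance alone; this is an interpretation, documented
   here, not a mathematically forced choice.
2. Hypothetical channel-response vectors for each position are obtained
   by circularly re-centring the symmetrized CTF on that position's
   channel (the inverse of the alignment step).
3. An arbitrary position on the circle is a weighted average of its two
   neighbouring positions' hypothetical vectors — equal weights for the
   midline midpoints (top between positions 8 and 1, right between 2
   and 3, bottom between 4 and 5, left between 6 and 7).
4. The topography is `W · response`, with `W` averaged across folds
   (and across the 260–270 ms analysis window). Fold-averaging before
   group-averaging is a documented choice; the alternatives differ only
   through estimation noise.

Validation against ground truth compares the reconstruction with
`GroundTruth.evoked_topography(angle)` — the generative model evaluated
at the held-out angle, *including* the mixing of neighbouring channel
topographies through the tuning profile. That is the right comparator
because a real evoked response at that position would carry the same
mixing; the bare single-channel bump is not observable in data.

## Cluster-based permutation statistics

Sample-wise two-sided t-tests (against a null value, paired, or
unpaired with pooled variance) feed max-statistic cluster correction:
samples with uncorrected p < `cluster_alpha` (default 0.05) form
clusters of contiguous time samples or connected electrodes of common
sign, scored by summed t; each observed |mass| is compared to the
permutation distribution of the maximum |mass|. Permutation units are
subject-level sign flips (one-sample/paired) or group-label exchange
(unpaired) — the standard nonparametric scheme for EEG group inference.
Positive and negative clusters are tested separately against the
max-|mass| null, realizing a two-tailed test.

When the full sign-flip group has no more elements than the requested
permutation count, it is enumerated exhaustively and p-values are exact
(`count / 2^n`, the identity included, so p > 0); otherwise random
permutations are drawn and p-values use the `(b+1)/(n_perm+1)`
convention, which avoids p = 0 and remains exact under exchangeability.
Zero-variance samples produce ±inf t-values, which are treated as
supra-threshold rather than raised, keeping degenerate electrodes
visible in the output.

Family-wise error was verified by simulation: over 500 null datasets
(8 subjects × 50 samples, exhaustive 256-flip null) the fraction of
datasets with any cluster p < 0.05 is statistically indistinguishable
from 0.05.

A caveat inherited from the analysis design: t-tests across subjects on
k-fold classification accuracies are fixed-effects statistics and do
not allow population-level inference; conclusions are restricted to the
tested sample. Prevalence-based statistics would be needed for
population claims.

## What the synthetic benchmark does and does not show

The generator reproduces the features the analyses rely on: a
position-tuned topographic signal with the right timing, graded overlap
between neighbouring positions, balanced designs, and two montage
layouts. It deliberately omits: biophysical volume conduction (bumps
are geometric, not dipolar), trial-to-trial latency/amplitude jitter,
1/f and oscillatory background activity, artifacts other than the
injected HEOG steps, and — importantly — **between-subject topographic
variability**: simulated "subjects" differ only in noise, so their
patterns are far more consistent than real subjects', which makes
group-level unpaired tests hypersensitive to tiny systematic shape
differences (visible as residual clusters even when reconstructed and
directly simulated patterns correlate at r ≈ 0.99). Passing tests
establish the correctness of the estimators and statistics, not the
effect sizes to be expected from real recordings.

## Problem sizes

Test and acceptance runs use desk-scale versions of the study designs:
40–96 trials per position, epochs −100..400 or −100..600 ms at 250 Hz,
500 simulated null datasets for the calibration check, and 256–1000
permutations per cluster test. These sizes were chosen so the full
validation runs comfortably on a laptop while keeping binomial/Monte
Carlo error well inside the asserted tolerances.
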