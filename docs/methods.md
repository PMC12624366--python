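# Methods

This note documents the models, parameters, and numerical choices behind
`touchdecode`, and what its synthetic-cohort validation does and does not
establish about real EEG data.

## Experimental design being emulated

The package targets rapid-serial visual-touch experiments: 90 base videos
of tactile hand interactions, each shown in 4 orientations (left/right
hand × self/other perspective), so 360 unique stimuli. Each subject views
32 sequences; every sequence presents each base video exactly once in one
of its orientations, and the orientation assignment is counterbalanced so
that each oriented stimulus occurs exactly 8 times overall (2880
non-target trials). Sequences additionally contain 1–9 target trials
(touch to a white object, counted by the subject, excluded from analysis)
with at least 12 non-targets between consecutive targets. Epochs run
−100…800 ms around each stimulus onset at 2048 Hz.

Two structural notes. First, with 90 non-targets per sequence, at most 8
targets can respect the 12-trial gap ((9−1)·12 = 96 > 90); the generator
therefore samples target counts from the requested 1–9 range clipped to
the feasible maximum, so every generated sequence satisfies both printed
constraints that can jointly hold. Second, the epoch window is half-open,
[−0.1, 0.8), so sample counts are integral at both 2048 Hz (1843) and
200 Hz (180); an inclusive 800 ms endpoint does not fall on either grid.

## Stimulus features

Categorical: orientation (4), hand (2), perspective (2), approach (2),
object type (28), material (8, including skin), touch type (12), contact
agent (hand/object). The three larger cardinalities are fixed by the
uniform chance levels they imply (1/28 ≈ 3.6%, 1/8 = 12.5%, 1/12 ≈ 8.3%);
the package ships default label lists of exactly those sizes because no
canonical enumeration exists. Continuous: arousal, threat, pain on a 1–10
rating scale, and valence — the first principal component of the
per-video percentages of raters categorizing the video as pleasant or
unpleasant (2-column PCA on centered percentages, sign-oriented so
pleasant-dominant videos score positive). With all percentage rows
identical the component is undefined and an error is raised.

Feature models are compared through representational dissimilarity
matrices: indicator dissimilarity (0/1) for categorical features,
absolute difference for continuous ones, rank-correlated (Spearman) over
the strictly-lower triangle. Zero-variance triangles yield NaN rather
than a fabricated coefficient.

## Synthetic EEG generator

Simulated epochs are a sum of declaratively specified effects plus noise:

- **categorical-pattern**: each level of the target feature receives its
  own unit-norm spatial pattern (seeded, hence identical across
  subjects); the trial's pattern is added as
  amplitude · pattern · envelope(t).
- **continuous-amplitude**: one pattern scaled by the standardized rating
  of the presented stimulus.
- **band-limited**: the categorical envelope multiplied by a sinusoid at
  the carrier frequency, so the information lives at one spectral bin.

The temporal envelope is a raised cosine supported on
[onset, onset + duration): smooth, compactly supported, and strictly
causal (exactly zero before onset), chosen because no ground-truth
waveform exists for the real effects. Noise is white Gaussian
(default SD 1 µV) plus 1/f-shaped noise (FFT-filtered white noise,
power ∝ 1/f, unit RMS, default scale 1 µV) — a standard stylization of
EEG background activity in which low frequencies dominate; an optional
per-subject multiplicative gain models inter-subject amplitude
variability. Target trials are simulated as pure noise since they are
excluded downstream.

What the generator does **not** emulate: volume conduction from cortical
sources, eye/muscle artifacts, autocorrelated inter-trial background
(trials are independent), non-stationarities over the session, and any
veridical relation between video content and neural response. Passing
tests therefore demonstrate that the *pipeline* is correct and calibrated
(no information → chance; injected information → recovered at the right
time, frequency, and scalp location), not that real effects of a given
size would be detected.

A consequence of the 1/f component worth knowing: after band-pass
filtering, 200 Hz resampling and 50 ms smoothing, the within-epoch signal
is dominated by slow drift, so decoding scores at neighboring time points
are strongly correlated and a subject's time-averaged null score has few
effective degrees of freedom. Null grand means remain exactly unbiased
(balanced accuracy averages per-class recalls over all classes present,
so its null expectation is 1/K regardless of class imbalance or
classifier bias), but between-subject spread is larger than naive
per-time-point counting suggests. Calibration checks therefore always
compare against chance in units of the empirical between-subject standard
error.

## Preprocessing

Order: common average reference → band-pass → resample → baseline →
moving average (the order the chain is described in for the emulated
experiment). Filters are 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), i.e. zero-phase, so effect onsets are not delayed; the
corner frequencies (0.1 and 100 Hz) are the only specified parameters.
Resampling is polyphase with linear-extrapolation padding; the output
length is the epoch duration times the target rate, rounded. The moving
average is a centered 10-sample uniform window whose edge windows shrink
to the available samples (no invented padding data). Each step is
toggleable; disabling all steps is the identity.

## Decoding

Cross-validation is leave-one-sequence-out: one fold per sequence, so
train and test trials never share a sequence. Within each fold and time
point, channels are standardized with train statistics (zero-variance
features map to zero in both splits), confounds are optionally removed by
OLS per channel/time with train-fit coefficients applied to the test
split, and then:

- categorical targets: LDA with Ledoit–Wolf analytic shrinkage toward the
  scaled identity (`solver="lsqr", shrinkage="auto"`), deterministic and
  parameter-free; balanced accuracy = mean per-class recall over classes
  present in the test labels. Folds whose training split lacks a class
  are skipped with a warning.
- continuous targets: ridge regression with penalty α = 0.5 on the
  standardized channels; score = Pearson correlation between the held-out
  predictions and the true ratings, computed within each test fold and
  averaged (a pooled-predictions mode exists behind
  `AnalysisConfig(fold_score_mode="pooled")`; fold-averaging is the
  default because it matches per-fold cross-validated scoring).

Confound residualization defaults to one joint design matrix
[1, entropy, luminance, deep_pc1] because joint removal is the stricter
control; `confound_mode="separate"` removes each confound in its own
single-regressor model sequentially. Collinear confound columns are
dropped with a logged warning. The deep-network component is consumed as
a provided per-stimulus vector; the package computes entropy (Shannon
entropy of the 256-bin grayscale histogram, bits) and mean luminance
(grand mean brightness) itself, by default from the first video frame
(deep features from the middle frame), with frame choice as a config key.

## Searchlight and spectral decoding

Searchlight clusters are each electrode plus its k = 4 nearest neighbors
by Euclidean distance in the packaged 2-D projected 64-channel layout
(neighborhood size is not externally specified; 5-channel clusters are a
standard small choice and k is configurable). Distance ties are broken
by channel-name order, logged. Scores are stored at the cluster center;
default time grid: −50…750 ms in 100 ms steps (9 points).

Spectra are rectangular-window FFT periodograms of the post-stimulus
0–800 ms segment at the acquisition rate. At 2048 Hz that segment holds
1638 whole samples, giving a true resolution of 2048/1638 ≈ 1.2503 Hz;
bins are labeled on the nominal 1.25 Hz grid (≤ 0.3% center mismatch) and
the DC bin is discarded, retaining k = 1…40 (1.25–50 Hz). The
post-stimulus segment is used because it is the stimulus-driven part of
the 900 ms epoch; no taper is applied since only an FFT is specified.
Power is energy-normalized (bins sum to Σx², Parseval), making power
invariant to DC offsets and quadratic in amplitude.

## Group inference

At each axis point the subjects' fold-averaged metrics minus chance enter
a one-sample JZS Bayes factor: H1 places a half-Cauchy prior (r = 0.707)
on the standardized effect d, truncated to d > 0.5 when the excluded
interval [0, 0.5] is active (prior mass renormalized — the
"omitted from the prior" reading), against H0: d = 0. The marginal
likelihood is computed by adaptive quadrature of the noncentral-t
likelihood over the prior (relative tolerance well below 1e-6; verified
against a dense trapezoid oracle to 1e-4 and against an independent
implementation of the two-sided case). The interval is applied for
time-resolved curves and disabled for topography and frequency axes,
where smaller effects are expected. An alternative interval treatment —
an interval-vs-interval Bayes factor (d > 0.5 against 0 ≤ d ≤ 0.5 under
the full prior) — is available via `interval_mode="interval-null"`; the
naive posterior/prior-odds rearrangement of the point-null test is
algebraically identical to truncation and therefore not a separate mode.
When the subject effects have zero variance (saturated decoders), the
limiting Bayes factor (∞, 1, or ~0 by the sign of the mean) is reported
instead of failing.

Onset is the earliest post-stimulus point where BF > 6 holds for at least
`min_run` = 5 consecutive samples (25 ms at 200 Hz) — "sustained" is not
externally defined, and 5 samples rejects single-point flickers; the peak
is the post-onset point of maximal group-mean metric. Both are absent
when no qualifying run exists.

## Problem sizes used in validation

The test suite and the acceptance script run the pipeline at reduced
scale, chosen so checks remain exact while each run stays in the minutes
range on one CPU: null-cohort calibration uses 10 subjects on the full
360-stimulus design with 4 sequences per subject in the test suite and 8
in the acceptance script (every sequence presents each base video once),
512 Hz acquisition, and a coarsened decoding time grid — none of which
moves a chance level; parameter
recovery uses 8-base-video designs with high-SNR injected effects
(single-subject peak accuracy > 0.8). Onset recovery tolerates ±25 ms,
which absorbs both the slow rise of the raised-cosine envelope (late
bias) and the 50 ms centered smoothing window (early bias).

## Known limitations

- The LDA shrinkage rule and the ridge-α convention are the
  scikit-learn ones; other implementations of "regularized LDA" may
  differ in decision values (not in the calibration properties tested).
- Searchlight neighborhoods use 2-D projected distances, not geodesic
  scalp distance.
- The generator's independence across trials understates the temporal
  autocorrelation of real recordings; leave-one-sequence-out folds are
  therefore *more* independent here than in real data.
- No multiple-comparison control beyond the Bayes-factor thresholds is
  applied, mirroring the evidence-curve approach the pipeline implements.
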