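# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the problem sizes the default test suite uses.

## Conventions

Amplitudes are microvolts throughout; times are seconds (milliseconds
only in ERP waveform axes and reaction times); sample indices are
0-based; every window and band interval is half-open `[start, end)`.
Sampling rates of 500 Hz (scalp/oddball) and 600 Hz (in-ear) are the
study-faithful defaults, but any positive rate is accepted.

## Preprocessing

Filters are 4th-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`), i.e. zero-phase, so component latencies
are unshifted; the cutoffs are 0.1–30 Hz for the scalp path and 2–30 Hz
for the in-ear band-power path. Only the cutoff frequencies are dictated
by the analysis being reproduced; Butterworth zero-phase is the field's
default realisation.

Epochs span −100…600 ms around each stimulus and are baseline-corrected
by the mean of [−100, 0) ms per channel. Amplitude rejection
(±50 μV for epochs, on EEG and EOG alike; ±100 μV for rest segments) is
applied to **post-filter, baseline-corrected** amplitudes — the source
description is ambiguous on this point, and rejection is described after
filtering, so that order is implemented and recorded here
(`preprocess.REJECTION_CONVENTION`). Rejection never mutates sample
data; it only flips keep flags and records a reason, so
kept + rejected = total always holds. Segments are strictly
non-overlapping and consecutive; a trailing remainder shorter than the
segment length is discarded.

## ERP quantification

The MMN and P300 are scored on the target-minus-standard difference
waveform. The literature phrase "area of the negative peak" is
self-contradictory (area vs peak); the package's primary measure is the
**polarity-clipped trapezoidal area**: `∫ min(x, 0) dt` over
[100, 250) ms for the MMN (≤ 0 by convention) and `∫ max(x, 0) dt` over
[240, 400) ms for the P300 (≥ 0), in μV·ms. The windowed extremum
amplitude and its latency are reported alongside for users who prefer a
peak measure. Note that the clipped-area estimator is biased under
residual noise (clipping pure noise contributes area); the test suite
accounts for this with a closed-form expectation
`E[min(s+ε,0)] = s·Φ(−s/σ) − σ·φ(s/σ)` when validating recovery at
realistic noise. Areas are computed per channel (Fz, Cz, Pz) with no
pooling. All target epochs enter the ERP average regardless of response
correctness; correctness gates only the reaction-time summaries.

## Spectral analysis

Each kept 8-s segment is transformed with a Hann-tapered periodogram
normalised so bin powers (μV²) sum to the window-weighted mean square
(Parseval-consistent); frequency resolution is 1/8 s = 0.125 Hz. The
Hann taper suppresses leakage that would otherwise corrupt the narrow
IAF-anchored bands. The IAF is the argmax of the
segment-and-channel-averaged pre-sauna spectrum over 8–13 Hz inclusive
(ties break to the lower frequency; the estimate lives on the spectrum's
grid). All pre-sauna rest data contribute (L and R averaged) — the
source does not specify a channel or sub-selection. Band powers are
**sums** (not means) of bin powers in each half-open band; the four
IAF-anchored bands therefore exactly partition [IAF−6, IAF+2), and
"gross absolute power" is reproducible without reference to bin width.
Sums and means are monotone-equivalent for the statistics.

## Decoder

Pipeline order is fixed and recorded on every fitted model:
`segment → fft_power → noise_screen → standardize → balance → split →
pca → lambda_cv → fit → test`.

* Features: 4-s segments of the 2–45 Hz-filtered recording (the wider
  band keeps the 30–40 Hz features meaningful; the 2–30 Hz band of the
  band-power path would null them); per segment, power at 0.5 Hz steps
  over 4.0–40.0 Hz (73 steps; the step at f sums periodogram bins in
  [f, f+0.5)) for L, R and the time-domain difference L−R: 219 columns.
* Noise screen: the published screening criteria were derived from a
  proprietary corpus of clean in-ear recordings and are not available;
  the operative rule here — a deliberate, documented deviation — is
  within-participant: segments whose total broadband power exceeds
  mean + 2 SD of that participant's segments are excluded (zero-variance
  sets keep everything).
* Standardisation: per-column z-scoring within participant, fit on
  training rows and applied to test rows. A `"global"` mode (fit on all
  rows, the literal reading of "standardised within participants") is
  available for comparison but leaks test statistics and is not the
  default.
* Balancing: the totonou class (three post sets vs one pre set) is
  subsampled without replacement to the non-totonou count, per
  participant, re-drawn per evaluation split.
* Classifier: PCA (full SVD, ≤ min(150, features, n−1) components, fit
  on training rows only), then "LDA with LASSO" realised as an
  L1-penalised least-squares fit on PCA scores with classes coded ±1 —
  for two balanced classes the least-squares direction coincides with
  the LDA discriminant, so the lasso is a faithful sparse-LDA surrogate
  and `sklearn.linear_model.lasso_path` computes the whole λ path
  cheaply. The λ grid is 50 log-spaced values from the null-model
  threshold `max|Zᵀ(y−ȳ)|/n` down three decades; 10-fold stratified CV
  on the training rows picks the λ with lowest mean misclassification,
  ties resolving to the larger (sparser) λ; final weights are refit on
  all training rows.
* Evaluation: stratified 90/10 splits. A single split is high-variance
  at these segment counts, so per-participant accuracy is the mean over
  20 seeded splits by default (`n_splits=1` recovers the single-split
  protocol). Group-level accuracy is the mean of participant means, with
  a one-sample t-test against 50 %.

## Group statistics

The mixed-design ANOVA is the univariate two-way decomposition
(between: group; within: set/stage) with the between-subjects error for
the group effect and the subject × within error ("MSe") for within and
interaction effects — this matches the reported F(df1, df2) structure
(e.g. F(3, 54) for 2×10 participants × 4 sets). Electrode location is
handled by averaging L/R (band powers) or analysing per channel (ERP),
not as a third factor; location never carried effects in the study this
reproduces. Requirements: balanced complete data (no imputation), ≥2
participants per group. No sphericity correction is applied by default
(none was reported). Simple main effects test the within factor per
group against the **pooled** within error term; Holm–Bonferroni pairwise
comparisons use `t = Δm / √(2·MSe/n)` on the pooled error df. Pairwise
tables are gated on a significant omnibus (interaction or within main
effect) plus a significant simple main effect in the group being probed,
mirroring standard post-hoc practice. Marginal significance (p < 0.1) is
flagged separately. Degenerate inputs (zero error variance) map to F = 0
when the effect is also zero and F = ∞ otherwise.

## Synthetic data

The generator reproduces the *statistical structure* the analyses
assume, not biophysics:

* Oddball sessions: a uniformly random arrangement of
  `round(n·fraction)` targets subject to the ≥2-standards gap constraint
  (stars-and-bars over the free gaps); Gaussian MMN/P300 deflections
  (σ = 20 ms; amplitudes validated to keep ≥90 % of their mass inside
  the scoring windows) added at target onsets; background is an
  equal-power mix of 1/f and white noise (default SD 8 μV); blinks are
  300 ms half-sines on EOG with 20 % bleed into scalp channels;
  reaction times are log-normal (median 400 ms, log-SD 0.2) plus an
  additive per-stage shift, correct with probability 0.95.
* In-ear rest: one band-limited filtered-noise oscillator per
  IAF-anchored band, each rescaled to a target absolute power, plus an
  amplitude-modulated sinusoid exactly at the IAF funded from half of
  the upper-alpha target (so the 8–13 Hz argmax is the injected IAF and
  each band's realised power stays proportional to its own target), a
  pink-noise floor, and 100 ms 150 μV bursts at a configurable rate to
  exercise the ±100 μV rejection.
* Cohorts: per-participant IAF ~ U(9, 11) Hz; base band powers
  log-normal around {theta 40, lower1 20, lower2 25, upper 25, beta 10}
  μV² (between-subject log-SD 0.3; the large theta scale mirrors the
  relative error-variance ordering of the study's bands); per-stage
  multiplicative jitter (log-SD 0.12) plays the role of within-subject
  error. Default sauna-group stage factors rise for theta/lower-1 alpha
  from post1 (×1.6/1.55 → ×1.85/1.8) and for lower-2/upper alpha from
  post2 only (×1 at post1), with beta flat — the target post-hoc
  pattern, at effect sizes chosen a priori to be generous (log-effects
  ≳ 3× the within-subject SD). The control group gets identity factors
  with the same jitter. ERP stage effects (sauna, post3): MMN −3 μV
  (larger magnitude), P300 −3.5 μV, RT −40 ms. Questionnaire scores are
  VAS values whose designated items (Q2, Q4, Q14) change, pre→post3,
  with correlation 0.77 to the participant's theta-power change;
  remaining items drift mildly.

Default desk-scale durations: 128 s of pre-sauna rest and 48 s per post
set (68 four-second decoder segments per participant; 16 + 3×6
eight-second spectral segments), 200-stimulus oddball sessions. These
are deliberate scaled-down stand-ins for typical ~7-minute rest periods;
passing tests therefore demonstrate correctness and calibration of the
*pipeline*, not field-realistic effect detectability, head-model
realism, alpha non-stationarity beyond slow AM, heartbeat/line-noise
artifacts, or any property of real in-ear recordings.

All simulation is deterministic given the design seed; per-participant,
per-stage child seeds come from `numpy` seed sequences.

## Test-suite problem sizes

Monte-Carlo tests are sized to keep the default suite a few minutes
long: the target post-hoc pattern is checked over 20 replicate
cohorts (10 per group); the null (identity-effects) calibration over 12
cohorts pooled across the five bands; ERP directional effects over 10
cohorts of 100-stimulus sessions; ANOVA type-I error over 2000 null
replicates of a 2×8×4 design against a ±2-binomial-SE band; the
decoder's chance anchor over 10 participants × 20 splits against a
±3-SE band; score-coupling recovery over 200 draws of the generator's
coupling step plus one full-cohort spot check. The ANOVA implementation
is verified against a loop-based brute-force sums-of-squares oracle on a
sweep of small balanced designs and against `pingouin.mixed_anova` as an
independent library oracle.

## Known limitations

* The decoder's noise screen and the "LDA with LASSO" surrogate are
  reconstructions of procedures whose exact definitions are not public
  (see above); both are recorded in the fitted model/config.
* `mixed_anova` requires balanced complete designs; unbalanced or
  incomplete data are rejected rather than approximated.
* EDF input requires the optional `mne` dependency; the package's
  canonical on-disk format is delimited text with a YAML sidecar, and
  EDF writing is not supported.
* Band intervals at shared edges are lower-inclusive by fiat; a bin
  falling exactly on the IAF belongs to upper alpha.
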