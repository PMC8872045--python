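# Methods

This note documents the models, parameter choices and numerical decisions
behind `eegemo`, and what the synthetic validation does and does not
establish about real recordings.

## Synthetic cohort model

Each participant-condition recording is a 4-channel (TP9, AF7, AF8, TP10)
signal in microvolts at 256 Hz, 300 s by default, built additively from:

* **1/f background** — Gaussian noise spectrally shaped to power ∝ 1/f
  (χ = 1), independent per channel, normalized to 4 µV RMS. This gives the
  canonical resting-EEG spectral slope and keeps every band power finite.
* **Five band oscillators** — sinusoidal carriers at the band midpoints
  (2.25, 6, 10, 21, 40 Hz) with baseline amplitudes 20/10/15/5/3 µV for
  δ/θ/α/β/γ, values typical of eyes-open resting EEG. Each carrier is
  amplitude-modulated by a slow (≤ 0.2 Hz) Gaussian envelope normalized to
  unit RMS, so the expected band power of an oscillator is exactly A²/2.
  Sixty percent of the envelope variance is shared between the two
  electrodes of a symmetric pair: this makes the per-epoch band-power
  series of a pair positively correlated, which is what gives the CC
  features non-degenerate values, and leaves 40 % channel-specific
  variation.
* **Condition effects** — multiplicative amplitude factors per band
  (power scales as the square) plus log-amplitude asymmetry offsets split
  ± between the right and left electrode of a pair. Defaults: high arousal
  α×0.7, β×1.6, γ×1.5; low arousal α×1.4; social anxiety θ×1.5, β×1.5 with
  a +0.4 frontal alpha-asymmetry offset; baseline is the identity. The
  directions follow the resting-EEG correlates of arousal and anxiety; the
  magnitudes are modelling assumptions — no quantitative effect sizes exist
  for this protocol — and are configurable. They were chosen once to give
  a graded difficulty profile (social anxiety easiest, baseline vs low
  arousal hardest) rather than uniform separability.
* **Participant random effects** — per-band log-normal amplitude
  multipliers (σ of the log = 0.2) drawn once per participant and shared
  across that participant's four conditions. This creates the
  between-subject variance that makes participant-grouped cross-validation
  meaningfully harder than row-wise splitting. The spread is a
  cohort-level parameter (it describes the population, not one condition).
* **Artifacts** — Poisson event streams: blinks (default 4/min) as
  0.3–0.5 s raised-cosine transients, frontal channels at 3× the
  temporoparietal amplitude; muscle bursts (2/min) of 30–70 Hz band-limited
  noise on one channel; spikes (1/min) as single-sample ±300 µV outliers.
  Each class is catchable by a distinct rejection rule (absolute amplitude,
  peak-to-peak, gradient).

Everything is a pure function of parameters and an integer seed; cohorts
derive per-recording seeds from a `SeedSequence` tree, so recordings are
independent but jointly reproducible.

What the generator does **not** emulate: hardware noise floors and
dry-electrode drift, line noise, Bluetooth dropouts, cardiac and ocular
rhythms beyond discrete blinks, non-stationary condition effects within a
recording, and any genuine neural coupling structure beyond the pairwise
envelope sharing. Tests passing on this generator therefore establish that
the *pipeline* is correct (features measure what they claim, selection
recovers planted signal, CV is leak-free), not that the classifiers would
reach comparable accuracy on human data.

## Preprocessing

Stage order is filter → segment → baseline-correct → reject → (optional
ICA). Baseline correction is defined per epoch (mean subtraction per
epoch-channel trace), so it must follow segmentation; this ordering is
deliberate. The band-pass is a 4th-order Butterworth (per pass) applied
forward-backward (`sosfiltfilt`), giving zero phase distortion of the
band-power estimates, < 0.1 dB ripple over 2–50 Hz, and ≈ 60 dB attenuation
at 100 Hz.

Visual artifact screening is replaced by deterministic thresholds: an epoch
is dropped iff any channel exceeds 100 µV absolute amplitude, 200 µV peak
to peak, 50 µV/sample gradient, or stays within a 0.5 µV flatline range.
With the default artifact rates ≈ 75–80 % of epochs survive. The thresholds
are conventional automated-rejection values, not calibrated to reproduce
any particular retention rate.

ICA cleaning (FastICA, ≤ 4 components, components removed when their
absolute correlation with a supplied artifact template exceeds 0.8) is
implemented and tested but off by default: the decomposition is stochastic
and the threshold rules already catch the injected artifact classes.

## Features

Band power uses one rectangular-window periodogram per 2-s epoch (0.5 Hz
resolution) in `spectrum` scaling, summed over half-open frequency
intervals [low, high), so the five bands partition [0.5, 50) Hz without
double-counting and an in-band sinusoid of amplitude A contributes A²/2.
Band edges are δ 0.5–4, θ 4–8, α 8–12, β 12–30, γ 30–50 Hz.

CC is the Pearson correlation across the retained-epoch band-power series
of a symmetric pair — the only reading that yields a single scalar per
band-pair after per-recording averaging. A zero-variance series is an
error, not a silent NaN.

Katz FD uses the standard waveform formulation: curve length
L = Σ|x(i+1)−x(i)|, extent d = max|x(i)−x(0)|, steps n = len−1,
D = log₁₀n / (log₁₀n + log₁₀(d/L)). This form is amplitude-scale
invariant, equals 1 exactly for monotone-linear traces, raises D with
irregularity, and makes a constant trace a well-defined degenerate case
(L = d = 0). FD is computed per 2-s epoch and averaged, mirroring the
band-power protocol.

## Selection

Features are standardized to zero mean and unit variance (constant columns
are a named error) and regressed on a single numeric response encoding
condition on an arousal-ordered scale (baseline 0, low 1, high 2,
social 3); a scalar coefficient per feature requires a scalar response,
and the ordering matches the intended arousal gradient. Regularization
strength is chosen by seeded internal 5-fold CV over a log grid
(10⁻⁴…10², 25 points). Rankings are by |coefficient| descending with
deterministic tie-breaking by column order; the selected set is the
intersection of the two top-20 prefixes, ordered by ridge rank. On default
synthetic cohorts the intersection typically contains 11–14 features.

## Classification and evaluation

Cross-validation folds partition participants (seeded shuffle, near-equal
chunks): all four rows of a participant share a fold, so no individual is
ever in both train and test — asserted on every fold of every run. A test
fold reduced to a single class is skipped with a warning and excluded from
the fold average.

Classifier defaults: XGBoost (η = 0.3, γ = 0, max_depth 6,
min_child_weight 1, 100 trees), SVC (RBF kernel, γ = auto, probability
outputs enabled for ROC), logistic regression (L2, Newton-CG). SVC and
logistic regression are preceded by a `StandardScaler` fitted on the
training fold only — an RBF kernel on raw µV² band powers is
scale-degenerate; XGBoost is scale-free and runs on raw features. XGBoost
uses `tree_method="exact"`: at 60 rows the classical greedy enumeration is
cheap and places split thresholds at gap midpoints rather than on data bin
edges, which matters when classes are widely separated.

Precision, recall, F1 and accuracy come from explicit confusion counts;
multiclass values are unweighted macro averages of one-vs-rest reductions,
with undefined per-class values (0/0) excluded from the mean under a
warning. In binary contrasts the later condition in the order
baseline < low < high < social is the positive class. AUROC is built by a
threshold sweep where tied scores cross together, making the trapezoidal
area equal the Mann–Whitney statistic with ties counted ½; multiclass
AUROC is macro one-vs-rest. Feature importances are XGBoost total gain,
averaged over folds, normalized to sum 1, top 5 reported.

The benchmark covers all 6 binary contrasts and 4 multiclass contrasts
(the three arousal-adjacent triples and the full four-class problem),
× 3 classifiers = 30 cells.

## Problem sizes

The default study is 15 participants × 4 conditions × 300 s at 256 Hz
(150 epochs per recording before rejection; a 60-row dataset), which is
what `scripts/acceptance.py` runs end to end in about a minute. The test
suite uses smaller cohorts (4–10 participants, 8–60 s recordings) chosen
so each statistical check retains adequate power: parameter-recovery and
spectral-fidelity checks average 32 seeded replicates, planted-feature
selection uses 50 replicates, permutation nulls 20.

## Known limitations

* Condition effect magnitudes are assumptions; absolute classifier scores
  on synthetic cohorts are properties of those assumptions, not estimates
  of real-world performance.
* The lasso/ridge intersection inherits the instability of lasso on
  correlated features (DASM/RASM/FP of one band are strongly dependent);
  the selected-set size varies by a few features across seeds.
* Recordings are written/read as CSV (and generated in memory); EDF export
  is not provided.
* With fewer participants than folds the benchmark refuses to run rather
  than silently degrading; pass a smaller `--folds`.
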