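# Methods

`eegdem` reconstructs, as a reusable and testable pipeline, a classical
approach to discriminating dementia stages from resting-state scalp EEG:
spectral features are extracted per electrode (either Fourier band
magnitudes or discrete-wavelet sub-band statistics, the latter after an
adaptive-threshold artifact attenuation), and a gain-ratio decision tree is
trained and validated on the resulting feature matrix. This note records the
model, the parameter choices, and the places where the design was genuinely
open.

## Recordings and preprocessing

Input is a 19-channel recording in the International 10-20 montage
(Fp1 … O2), 300 s at 256 or 1024 Hz, in microvolts. Preprocessing keeps the
central 180 s — the half-open sample window `[60·fs, 240·fs)`, which holds
exactly `180·fs` samples — to avoid start/end-of-session artifacts, then
resamples to 256 Hz by polyphase rational resampling with a Kaiser-windowed
anti-alias low-pass at the target Nyquist. Any standard anti-aliased method
would do; polyphase resampling was chosen because it is exact for rational
rate ratios (1024→256 is a plain factor-4 decimation) and preserves
band-limited signal power to well under 1 %.

## Synthetic cohort

Clinical EEG of this kind is rarely shareable, so the package ships a
generator that emulates the *spectral* signature the classifier is supposed
to exploit: Alzheimer's disease (AD) EEG shows increased delta/theta and
decreased alpha/beta activity relative to healthy controls (HC), with mild
cognitive impairment (MCI) intermediate. Each channel of a synthetic subject
is

* one narrow-band oscillation per canonical band (delta 0.5–4 Hz, theta
  4–7 Hz, alpha 8–13 Hz, beta 13–30 Hz), built as the sum of three random
  tones inside the band with random phases — band-limited but not tonal, and
  with peak amplitude bounded by the configured band amplitude;
* 1/f background noise (spectrally shaped white noise, exponent 1.0,
  RMS 12 µV);
* sparse spike artifacts: Poisson-placed (4 per minute per channel)
  isolated triangular transients of 50–100 ms, 120 µV peak.

Baseline band amplitudes are 20/15/35/12 µV for delta/theta/alpha/beta,
inside the amplitude ranges conventionally quoted for these rhythms. Class
structure enters as multiplicative band gains relative to HC (all ones):
AD 1.4/1.5/0.6/0.7 and MCI 1.2/1.25/0.8/0.85 for delta/theta/alpha/beta.
No quantitative effect sizes exist for these alterations in the source
setting; the gains are free parameters chosen once so that the class signal
is recoverable by the pipeline, and they are deliberately strong enough that
a failure of recovery indicates a pipeline defect rather than an underpowered
simulation. A per-subject log-normal amplitude jitter (σ = 0.15, shared
across channels) emulates inter-subject variability. Default cohort
composition is 49 AD / 37 MCI / 23 HC (109 subjects).

What the generator does **not** emulate: inter-channel correlation and scalp
topography, realistic artifact morphology (eye blinks, EMG), non-stationarity
beyond tone beating, and age/sex covariates. Passing tests therefore show
that the pipeline recovers a band-power class signal under realistic noise
and artifact levels — not that it would reach any particular accuracy on
clinical data.

All randomness flows from a master seed; subject `i` is generated from the
stream `(seed, i)`, so cohorts are reproducible and subjects independent.

## Fourier features

The discrete Fourier transform X[k] = Σ_s x[s]·e^(−j2πks/S) (computed by
FFT, contractually equal to the direct sum) is reduced to 16 coefficients
per electrode: the signal is split into 4 non-overlapping 45 s epochs; the
per-epoch magnitude spectrum is averaged within 16 equal-width 2 Hz bins
spanning (0, 32] Hz (DC excluded, so the features are offset-free), and bins
are averaged across epochs. 19 electrodes × 16 = 304 features. How a
46 080-point spectrum is best summarized in 16 numbers is an open design
point; equal-width band magnitudes over the delta-to-low-gamma range were
chosen because they are scale-stable, interpretable as band activity, and
tile the clinically relevant bandwidth. Epoch count and `f_max` are
configurable.

## Wavelet features and artifact attenuation

**Attenuation.** Each channel is decomposed with a sym3 DWT to depth 8
(symmetric boundary extension). For a sub-band signal x the adaptive
thresholds are `thr_up = avg(x) + 1.5·stdev(x)` and
`thr_dwn = avg(x) − 1.5·stdev(x)` (sample standard deviation, n−1), and any
sample outside the interval is multiplied by `(thr_up − thr_dwn)/100` —
attenuated, not zeroed. The rule is applied to the *time-domain band-limited
reconstructions* of the level-5 and level-8 detail sub-bands (4–8 Hz and
0.5–1 Hz at 256 Hz), and the channel is reassembled. Two details matter:

* *Domain.* On the microvolt scale of scalp EEG the factor
  `(thr_up − thr_dwn)/100 = 3·sd/100` is ≈ 0.1–0.5, so flagged samples
  shrink. Applied to raw orthonormal DWT coefficients — whose magnitude
  grows as 2^(level/2) — the same factor exceeds one and would *amplify*
  outliers. The time-domain sub-band form is therefore the only reading
  under which the rule attenuates at physiological amplitudes, and is the
  one implemented.
* *Selectivity.* A steady oscillation of amplitude A has sd = A/√2, so
  1.5·sd ≈ 1.06·A and the rhythm itself stays inside the thresholds;
  sparse high-amplitude transients cross them and are crushed. Content of
  the targeted bands whose envelope fluctuates (beating tones, broadband
  noise — for a Gaussian sub-band, more than half the variance lies beyond
  ±1.5σ) is partially attenuated *by design*: the method trades some genuine
  theta/slow-delta energy for artifact robustness. Measured on artifact-free
  multi-tone synthetic channels this costs on the order of 5–9 % of overall
  RMS; on alpha/beta-dominant channels (attenuated bands empty) the signal
  passes through essentially unchanged (< 5 % RMS).

Thresholds are computed once per whole channel (not per epoch); windowed
variants were evaluated and do not change the behavior measurably.

**Features.** The denoised channel is split into 4 epochs; each epoch gets a
db4 decomposition to depth 5, whose dyadic sub-bands approximate the rhythms
at 256 Hz: A5 → delta (0–4 Hz), D5 → theta (4–8 Hz), D4 → alpha (8–16 Hz),
D3 → beta (16–32 Hz). (A dyadic filter bank cannot match the nominal
clinical band edges, e.g. alpha 8–13 Hz; this is the standard db4@256 Hz
convention.) Per band, three statistics of the coefficients: mean, sample
standard deviation, and power (mean squared coefficient — an epoch-length-
invariant PSD estimate). 3 × 4 bands × 4 epochs = 48 features per electrode,
912 for the montage. The count decomposes as stats × bands × epochs; two-band
variants (alpha–theta or beta–delta) are expressible by restricting the band
set but are not the default.

## Classifier

A from-scratch C4.5-style tree, because the deliverable is a *readable*
model: binary numeric splits chosen by maximizing the gain ratio
(information gain divided by the split's intrinsic information) over all
midpoint thresholds, with at least `min_leaf = 2` training instances per
side; ties broken by lower feature index, then lower threshold, making
training deterministic and row-order invariant. Values equal to a threshold
route to the "≤" branch. After growth, bottom-up pessimistic pruning
replaces a subtree by a leaf when the leaf's estimated errors (n times the
binomial upper confidence bound at cf = 0.25; the error-free case uses the
exact bound 1 − cf^(1/n)) do not exceed the subtree's. Subtree raising is
omitted. Trees serialize to JSON and export as annotated if/then rules
(leaf instance counts `(n/m)`), which re-parse to an exactly equivalent
classifier.

Feature ranking uses information gain after equal-width discretization into
10 bins per feature, ties broken by feature index.

## Evaluation

Four binary problems: HC vs AD, HC vs MCI, MCI vs AD, and HC vs CASE
(CASE = MCI ∪ AD). Schemes: leave-one-out (n folds), stratified seeded
10-fold, and a stratified seeded 90/10 holdout. Per-fold predictions are
pooled into one confusion matrix; accuracy, precision, sensitivity,
specificity and F-measure are reported in percent. Precision, sensitivity,
specificity and F-measure are support-weighted averages over the two classes
(per-class values are kept alongside); under this weighting sensitivity
equals accuracy. When information-gain selection is requested it runs
strictly inside each training fold — the held-out samples never influence
the ranking — which may be stricter than evaluation protocols that select
features once on the full matrix.

The permutation control shuffles the label column (class sizes preserved)
and reruns the full cross-validation, by default 100 times; a genuine class
signal shows as the real-label accuracy exceeding the permutation
distribution, whose mean should sit in the chance band.

## Problem sizes used by the test suite and acceptance script

The shipped checks run entirely on synthetic data: the default 109-subject
cohort at full length (300 s, 256 Hz) for the structural counts and the
class-signal recovery (10 master seeds for the wavelet-vs-Fourier
comparison); a balanced 20 + 20 cohort with 20 label permutations for the
chance-band control; 20 spiked 30 s channels for the attenuation check; and
100–200 random signals for the transform oracles (naive DFT sum, exhaustive
split enumeration, direct entropy, perfect reconstruction). These sizes are
the package's own choices and are stated here so results can be reproduced
exactly.

## Known limitations

* The 16-coefficient Fourier summary and the 48-coefficient wavelet layout
  are documented reconstructions of under-specified descriptions; other
  summaries are defensible.
* The attenuation rule's `/100` scaling ties its strength to the numeric
  scale of the data (microvolts here); data in other units would attenuate
  more or less aggressively.
* Gain-ratio maximization over all candidates (without the classic
  mean-gain pre-filter) can favor unbalanced splits on small noisy nodes;
  pruning mostly repairs this.
* LOOCV on small cohorts has high variance; the chance band for permuted
  labels is correspondingly wide (40–65 %).
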