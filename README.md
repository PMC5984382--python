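# eegdem

Interpretable EEG classification of dementia stages: spectral feature
extraction (Fourier band magnitudes, or discrete-wavelet sub-band statistics
with adaptive-threshold artifact attenuation) followed by human-readable
gain-ratio decision trees, validated with cross-validation and
label-permutation controls. A synthetic-cohort generator makes the whole
pipeline testable end to end without clinical data.

## The problem

Resting-state scalp EEG of Alzheimer's disease (AD) patients shows a
"slowing of the rhythms": more delta (0.5–4 Hz) and theta (4–7 Hz) activity,
less alpha (8–13 Hz) and beta (13–30 Hz), with mild cognitive impairment
(MCI) intermediate between AD and healthy controls (HC). `eegdem` turns a
19-channel 10-20-montage recording into a per-electrode spectral feature
vector and trains a C4.5-style decision tree to separate the diagnostic
classes — producing, instead of a black box, rules such as
*"if F4 alpha-band variability ≤ θ then AD"* that a clinician can read.

Two feature extractors are provided:

* **Fourier** — the DFT X[k] = Σₛ x[s]·e^(−j2πks/S), summarized as 16
  band-magnitude coefficients per electrode (2 Hz bins over (0, 32] Hz,
  epoch-averaged): 304 features per subject.
* **Wavelet** — channels are first denoised by an adaptive rule: in the
  sym3 DWT sub-bands at levels 5 and 8, samples outside
  avg(x) ± 1.5·stdev(x) are attenuated to s·(Thr_up − Thr_dwn)/100; then a
  db4 level-5 decomposition maps sub-bands to rhythms
  (A5→delta, D5→theta, D4→alpha, D3→beta) and mean, standard deviation and
  power of each band's coefficients are taken per 45 s epoch: 48 features
  per electrode, 912 per subject.

Trees are trained with gain-ratio splits and pessimistic pruning (J48-style
defaults: `min_leaf=2`, `cf=0.25`) and evaluated by leave-one-out,
stratified 10-fold, or 90/10 holdout on four binary problems (HC vs AD,
HC vs MCI, MCI vs AD, HC vs CASE where CASE = MCI ∪ AD), reporting
accuracy, precision, sensitivity, specificity and F-measure. A permutation
control re-runs the evaluation under shuffled labels to verify that real
accuracy exceeds chance.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from eegdem import (SyntheticCohortConfig, generate_cohort, cross_validate,
                    make_problem, train_c45, export_rules)
from eegdem.pipeline import extract_features

recs, labels = generate_cohort(SyntheticCohortConfig(seed=1))   # 109 subjects
fm = extract_features(recs, labels, "wavelet")                  # 109 x 912
binary = make_problem(fm, "HCvsAD")                             # 72 rows
print(cross_validate(binary, scheme="loocv", problem="HCvsAD").summary())
print(export_rules(train_c45(binary)))
```

prints

```
HCvsAD [loocv, 72 folds] classes=AD/HC
  Accuracy      86.1 %
  Precision     85.9 %
  Sensitivity   86.1 %
  Specificity   79.6 %
  F-measure     85.9 %
if F4_e4_alpha_std <= 40.93838239008453 then AD (48/1)
if F4_e4_alpha_std > 40.93838239008453 and Fp1_e1_delta_psd <= 7048.981549328912 then HC (22)
if F4_e4_alpha_std > 40.93838239008453 and Fp1_e1_delta_psd > 7048.981549328912 then AD (2)
```

— the 109-subject synthetic cohort is reduced to the 72-sample HC-vs-AD
problem, leave-one-out cross-validation pools 72 held-out predictions into
the five metrics (86.1 % accuracy here), and the full-data tree compresses
to three rules: AD subjects are flagged by low alpha-band variability at F4,
with a frontal delta-power check separating the remainder. Leaf annotations
`(n/m)` give the training instances reached and misclassified per rule.

The same pipeline is available from the shell:

```sh
eegdem simulate --out-dir cohort --seed 1
eegdem extract --method wavelet --in-dir cohort --labels cohort/labels.csv --out features.csv
eegdem evaluate --features features.csv --problem HCvsAD --scheme loocv --report report.json
eegdem permute  --features features.csv --problem HCvsAD --n-perm 100 --seed 1
eegdem run --out-dir runs/demo --seed 1     # everything, one command
```

`eegdem preprocess` trims a 300 s EDF/CSV recording to its central 180 s and
resamples to 256 Hz; `eegdem train` writes the model JSON and its rules.

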