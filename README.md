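# cowmotion

Detection of **active mounting** — the key behavioral sign of estrus — in
free-grazing dairy cattle from collar-mounted inertial sensors, and a
quantitative comparison of two ways of referencing the accelerometer
signal: the sensor-fixed **body frame (BF)** and the Earth-fixed **world
frame (WF)** obtained by rotating each sample with the collar's fused
orientation quaternion.

The package is organized as an analysis project: the library under
`src/cowmotion/` holds every computation, the numbered drivers under
`analysis/` run the study end to end, and `tests/` checks each stage
against independent oracles.

## The method

Each labeled event (active mounting, walking, resting, grazing, head
nodding; 10 Hz sampling) is cut into fixed 7-s windows. From every window,
14 time/frequency features — mean, median, standard deviation,
zero-crossing rate, peak-to-peak, sum, sum of absolute values, RMS, mean
absolute successive difference, skewness, kurtosis, mean time between
local maxima, dominant frequency, and the periodogram density at that
frequency — are computed on 8 channels (aₓ, a_y, a_z, |a|, ωₓ, ω_y, ω_z,
|ω|), giving a 112-dimensional vector **x** and a binary label y (1 =
mount, 0 = anything else).

Because mounts are rare, the majority class is randomly undersampled to
the mount count. A linear-kernel SVM (regularization C grid-searched on a
stratified 80 % split) is then scored with stratified 5-fold
cross-validation repeated 20 times — 100 fits — recording accuracy,
precision, recall and F1 per iteration:

    Accuracy = (TP+TN)/(TP+TN+FP+FN)   Precision = TP/(TP+FP)
    Recall = TP/(TP+FN)                F1 = 2·P·R/(P+R)

The BF and WF pipelines share the same events, balancing draw and fold
assignments, so their two 100-value F1 distributions are paired. They are
compared with Shapiro–Wilk / Levene assumption checks followed by a
t-test or Mann–Whitney U test with the rank-biserial correlation
r = 1 − 2U/(n₁n₂) as effect size. Sequential backward selection (SBS)
optionally prunes the feature bank, removing at each step the feature
whose absence leaves the highest cross-validated F1.

Because the field recordings may not be at hand, `cowmotion.synthetic`
generates a five-behavior database with the same structure: behavior
motion defined in the world frame (mounts as two high-energy peaks around
a quiet middle, walking as rhythmic horizontal oscillation, nodding as
vertical oscillation, grazing as random bursts, resting as near-silence),
mapped into an arbitrary, slowly wobbling collar orientation, with exact
BF↔WF consistency and optional raw ADC-count encoding.

## Worked example

```sh
cowmotion simulate --out scratch/db --counts mount=21,walk=186,rest=83,nod=43,graze=82 --seed 42
cowmotion run --db scratch/db --seed 1 --out results
```

or equivalently through the numbered drivers:

```sh
python analysis/01_simulate_database.py   # synthetic database, study-sized
python analysis/02_extract_features.py    # 415 x 112 design matrices
python analysis/03_train_evaluate.py      # balance, grid search, 100-fold CV
python analysis/04_feature_selection.py   # permutation screen + SBS to 13
python analysis/05_compare_frames.py      # BF vs WF statistics
```

On the default synthetic conditions the run prints

```
| frame   |   accuracy |   precision |   recall |    f1 |    C |
|:--------|-----------:|------------:|---------:|------:|-----:|
| body    |      100.0 |       100.0 |    100.0 | 100.0 | 0.01 |
| world   |      100.0 |       100.0 |    100.0 | 100.0 | 0.01 |
```

i.e. the default behavior signatures are fully separable in both frames:
every one of the 100 cross-validation iterations classifies the balanced
42-sample set perfectly, and the frame comparison consequently reports no
difference (Mann–Whitney U = 5000, p = 1, rank-biserial 0). The contrast
between frames appears when the mount signature is degraded toward the
head-nodding signature (`cowmotion.synthetic.interpolate_profiles`): mean
F1 falls monotonically into the mount/nodding confusion regime (~0.77 when
the two profiles coincide), the failure mode the detector has on real
collars. Per-behavior false-positive tables quantify exactly that
confusion.

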