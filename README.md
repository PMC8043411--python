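# screamcalls

Psychoacoustic and perceptual-decision analyses of human scream calls.

Human screams are not a single alarming signal: listeners distinguish at
least six scream types — pleasure, sadness, joy, pain, fear, anger — plus an
intense but neutral vocalization used as a baseline. This package implements
the analysis chain used to characterize that diversity, for researchers in
bioacoustics and auditory psychophysics who want a tested, reusable, and
fully synthetic-data-testable version of each stage:

- **Stimulus standardization** (`audio_prep`): RMS normalization to a common
  nominal level, fixed-duration cropping with intensity ramps, and
  quantification of the per-clip loudness-normalization delta in dB.
- **Roughness / modulation power spectrum** (`mps`): the MPS is the squared
  magnitude of the 2D Fourier transform of a Gaussian-window, log-frequency,
  log-amplitude spectrogram — power as a function of temporal modulation
  ωt (Hz) and spectral modulation ωs (cycles/octave), truncated at 200 Hz
  and 12 cyc/oct. Scream-like "roughness" lives in two temporal-modulation
  bands, ~60 Hz (50–70) and ~160 Hz (140–180). The module provides band
  powers, per-bin group contrasts with a label-shuffling permutation null
  (p = (1 + #{|Δperm| ≥ |Δobs|}) / (nperm + 1)), and an OLS regression of
  alarm ratings on the two band powers.
- **Acoustic classification** (`classify`): z-normalized feature tables
  (e.g. an 88-feature voice set), a 1-vs-1 third-order-polynomial SVM,
  stratified 5-fold cross-validation in which every sound is tested exactly
  once, and cross-classification between vocalization corpora in both
  directions.
- **Alarm categorization search** (`alarm_split`): all 25 admissible
  partitions of the six scream types into two categories of 2–4 types
  (neutral always forms a third level), each scored by a one-way
  repeated-measures ANOVA on per-rater mean alarm ratings; the maximum-F
  partition is the data-driven alarm/non-alarm categorization.
- **Behavioral decision metrics** (`behavior`): confusion matrices from
  7-alternative forced-choice logs, the categorization false-alarm rate
  (probability a category is chosen during misclassification), one-vs-rest
  sensitivity d′ = Z(hit rate) − Z(false-alarm rate), RT/accuracy summaries
  at 7-level and 3-level groupings, the 21-pair 2AFC discrimination analysis
  with paired t tests and Benjamini–Hochberg FDR, and the 4-way
  combination-category contrast.
- **Statistics core** (`stats`): repeated-measures ANOVA with Mauchly's
  sphericity test and a Greenhouse–Geisser correction applied when Mauchly
  rejects at p < .05, partial η², paired t, BH-FDR, Pearson correlation,
  OLS, and the inverse-normal quantile.
- **Synthetic data** (`synth`): generators that plant exactly the structure
  each stage detects — clips whose envelope carries band-limited amplitude
  modulation in a chosen roughness band, feature tables with configurable
  class separation, rating tables with a planted alarm partition, and
  forced-choice logs with a configurable confusion structure, log-normal
  RTs, and a miss rate.

## Worked example

```python
import numpy as np
from screamcalls import synth, mps, alarm_split, classify, behavior
from screamcalls.synth import ScreamSpec

# a synthetic fear scream with 55-65 Hz envelope modulation
clip = synth.make_scream_clip(ScreamSpec("fear", am_band=(55, 65), am_depth=0.8), seed=1)
grid = mps.compute_mps(mps.spectrogram_log(clip))
print(f"low-band (50-70 Hz) power:  {mps.band_power(grid, 50, 70):.2f}")
print(f"high-band (140-180 Hz) power: {mps.band_power(grid, 140, 180):.2f}")

# the exhaustive alarm categorization search on planted ratings
planted = alarm_split.CategorySplit({"pain", "fear", "anger"},
                                    {"pleasure", "sadness", "joy"})
ratings = synth.make_rating_table(planted, n_raters=23, seed=1)
best, second = alarm_split.best_split(ratings)[:2]
print(f"best split: {best.split}  F(2,44) = {best.f_value:.2f}")
print(f"runner-up:  {second.split}  F = {second.f_value:.2f}")

# SVM classification of a 420 x 88 synthetic feature table
table = classify.znormalize(synth.make_feature_table(7, 60, 88, separation=3.0, seed=1))
res = classify.crossval_classify(table, n_folds=5, seed=1)
print(f"5-fold CV accuracy: {100*res.overall_accuracy:.1f}% (chance {100*res.chance_level:.1f}%)")

# signal-detection sensitivity from a confusion matrix
conf = behavior.ConfusionMatrix(np.array([[84, 16], [16, 84]]), ("a", "b"))
print(f"d' at hit .84 / FA .16: {behavior.dprime_table(conf).table.loc['a','d_prime']:.3f}")
```

Output:

```
low-band (50-70 Hz) power:  293.32
high-band (140-180 Hz) power: 10.84
best split: {pain+fear+anger} vs {pleasure+sadness+joy}  F(2,44) = 9962.60
runner-up:  {fear+anger} vs {pleasure+sadness+joy+pain}  F = 9110.74
5-fold CV accuracy: 76.0% (chance 14.3%)
d' at hit .84 / FA .16: 1.989
```

The planted 60-Hz modulation dominates the low roughness band by more than
an order of magnitude; the exhaustive search over all 25 categorizations
returns the planted {pain, fear, anger} alarm partition first, with the
fear+anger variant as runner-up; at moderate class separation the SVM sits
far above the 14.3 % seven-class chance level; and the d′ value is the
textbook 2 × Z(0.84) ≈ 1.989.

## Command line

```bash
screamcalls all --demo --out runs/demo --seed 1      # full synthetic run
screamcalls simulate --out runs/s1 --seed 1          # corpus + tables only
screamcalls all --config myrun.yaml                  # config-driven run
```

Every run writes a `manifest.json` with a content checksum per output
file; identical configs and seeds reproduce identical checksums.

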