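# Methods

This note documents the models, numerical choices, and design decisions
behind each analysis stage, the way a statistics or acoustics package
documents its internals. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Stimulus standardization

Clips are cropped to a fixed duration (default 0.8 s) with linear intensity
ramps (default 15 ms) whose first and last samples are exactly zero, and
scaled so their RMS matches a common target. Absolute sound pressure level
is not recoverable from digital audio, so the package fixes a documented
reference convention: a nominal level of 70 dB maps to a digital RMS of
0.05, with other levels scaling as 20·log10 around that anchor. Every
downstream analysis depends only on clips sharing one RMS, not on the
anchor itself. If normalization would push samples beyond ±1, the clip is
returned at the exact target RMS with a warning rather than hard-clipped —
clipping would distort precisely the modulation content the MPS stage
measures. Linear (not cosine) ramps were chosen as the simplest shape
satisfying the zero-endpoint contract. The loudness delta is
20·log10(RMS_original / RMS_normalized) in dB; RMS dB is used as the
loudness measure throughout (no ISO 532 loudness model).

## Modulation power spectrum

The spectrogram uses Gaussian analysis windows (support ±4 SD) on a
log-spaced frequency axis (default 128 bins from 100 Hz to min(8 kHz,
Nyquist)), log-amplitude in dB floored 80 dB below the clip maximum. The
magnitudes of the short-time transform are computed on the linear FFT grid
and linearly interpolated onto the log axis. The MPS is |FFT2|²/N of the
mean-removed log-spectrogram (mean removal keeps the DC bin from dominating;
group differences are unaffected). Under this normalization total MPS power
equals the squared norm of the mean-removed log-spectrogram (Parseval,
asserted in tests). Axes follow from the Fourier pairs of the spectrogram
axes: temporal modulation in Hz from the hop, spectral modulation in
cycles/octave from the octave spacing of the frequency bins. The grid keeps
the nonnegative-ωs half-plane (the full plane is Hermitian-redundant for
real input) with both ωt signs, truncated at 200 Hz and 12 cycles/octave.

**Window length is the critical parameter.** A Gaussian window of SD σ
multiplies the envelope spectrum by a Gaussian of SD 1/(2πσ): at σ = 8 ms
the transfer SD is ≈ 20 Hz, which annihilates both roughness bands
(50–70 Hz, 140–180 Hz) before the MPS ever sees them. The default is
σ = 1 ms (transfer SD ≈ 159 Hz), which passes both bands at the price of
coarse spectral resolution (≈ 159 Hz) — the usual trade-off of modulation
analysis, resolved here in favor of the temporal axis because the analysis
targets temporal roughness. The default hop of 2 ms puts the
temporal-modulation Nyquist at 250 Hz, above the 200 Hz truncation bound.

Band power is the arithmetic mean of MPS power (not log power) over bins
with |ωt| inside the band, across the full ωs range; folding to |ωt| makes
band power invariant under time reversal. The group contrast is the per-bin
difference of group means (no t-statistic; the choice is immaterial for a
permutation null of equal group sizes), and the permutation test shuffles
group labels over the pooled grids preserving group sizes. P-values use the
add-one estimator p = (1 + #{|Δperm| ≥ |Δobs|})/(nperm + 1), which is a
valid finite-sample p-value and never exactly zero; its exact null level at
α with n permutations is ⌊α(n+1)⌋/(n+1), which the calibration tests use.
The default permutation count is 2000. The alarm-rating regression is OLS
with an intercept on the two band powers (the regression's covariate set is
a design choice; an intercept is the conventional default).

## Acoustic classification

Feature tables are z-normalized per feature across all sounds (sample SD;
constant features are zeroed with a warning since they carry no
information). The classifier is a support vector machine with a
third-order polynomial kernel in a 1-versus-1 multiclass scheme.
Hyperparameters are fixed and documented rather than tuned: C = 1,
gamma = 'scale', and kernel offset coef0 = 1 — the inhomogeneous
polynomial kernel, which is the common toolbox default. The homogeneous
variant (coef0 = 0) cannot represent affine decision boundaries and
demonstrably fails on linearly separable Gaussian clusters, so it is not
used. Voting over the pairwise decisions is implemented in the package so
that ties break deterministically toward the lowest class index in the
canonical category order. Cross-validation is stratified within class,
seeded, and recorded in the result, so each sound is tested exactly once;
cross-classification fits on one full corpus and evaluates on the other,
in both directions separately. Numeric equality with accuracies obtained
by other SVM toolboxes on other data is not a goal; the contracts are
chance-level calibration under label shuffles and near-perfect accuracy on
well-separated synthetic classes.

## Alarm categorization search

The six non-neutral scream types admit 25 unordered partitions into two
categories of 2–4 types (15 of shape 2-vs-4 and 10 of shape 3-vs-3);
neutral always forms a fixed third level and never enters the permutation.
Each partition is scored by a one-way repeated-measures ANOVA on per-rater
mean ratings over the three levels, and partitions are ranked by F. The
ANOVA is symmetric in the two categories, so splits are treated as
unordered; after scoring, the higher-rated side is reported as the alarm
category.

**Identifiability.** With category gap g and the neutral level sitting h
below the non-alarm category, the expected between-level sum of squares of
the planted 3-3 partition exceeds that of its strongest 2-vs-4 competitors
by g²/8 − g·h/6. The margin therefore shrinks as neutral falls below both
categories and grows when neutral sits between them; with neutral at the
category midpoint the planted partition is uniquely identifiable and the
recovery tests use that configuration. With neutral far below both
categories the runner-up partitions approach the winner and rank-1 recovery
degrades to roughly 80–97 % — the same near-tie structure that real alarm
ratings produce, where the best and second-best categorizations differ by
well under one percent in F. The generator's default rating means remain
domain-faithful (alarm 0.8, non-alarm 0.2, neutral 0.1).

## Behavioral decision metrics

Missed trials (no response inside the window, default 3000 ms) are excluded
from confusion counts, from RT means (which also exclude incorrect trials),
and from accuracy denominators. The false-alarm rate follows the
categorization usage: a category's off-diagonal choices divided by all
off-diagonal choices, summing to 1 across categories. Sensitivity is
one-vs-rest per category: hit rate from the category's own row,
false-alarm rate from all other rows pooled (trial-weighted), with extreme
rates corrected by the 1/(2N) rule (0 → 1/(2N), 1 → 1 − 1/(2N)) before the
inverse-normal transform. The 3-level grouping pools member types' trials
per participant (trial-weighted), asserted in tests against a direct
trial-level computation. In the 2AFC analysis each of the 21 type pairs
gets per-participant per-type means, a paired t across participants, and a
normalized difference (the per-participant difference divided by the
per-participant mean of the two types, averaged); Benjamini–Hochberg
adjustment is applied across the 21 tests with the RT and accuracy families
adjusted separately, the conservative reading when the family definition is
ambiguous. The 4-way combination contrast maps pairs to neutral-vs-scream
(6 pairs), within-non-alarm (3), alarm-vs-non-alarm (9), and within-alarm
(3), then runs a 4-level repeated-measures ANOVA on per-participant class
means. No RT trimming is applied beyond the response window.

## Statistics core

The repeated-measures one-way ANOVA uses the standard within-subject
decomposition. Sphericity is tested (k ≥ 3) with Mauchly's W on orthonormal
(Helmert) contrasts, using the chi-square approximation with the standard
second-order term of Mauchly's asymptotic expansion (the same expansion
ezANOVA and pingouin use; the package's implementation is cross-checked
against pingouin in the test suite). The Greenhouse–Geisser ε =
tr(S)²/((k−1)·tr(S²)) multiplies both degrees of freedom only when Mauchly
rejects at p < .05; ε is clipped to [1/(k−1), 1] and always reported. The
effect size is partial η² = SS_effect/(SS_effect + SS_error), chosen and
documented prominently because η² flavors differ across packages. For
k = 2 the F reduces exactly to the squared paired t (asserted at 1e−9).
Degenerate inputs: identical levels give F = 0; a singular contrast
covariance with nonzero effect yields F = ∞ with p = 0; Mauchly on a
singular covariance reports p = 0 (sphericity certainly violated). FDR is
Benjamini–Hochberg step-up via statsmodels, validated exactly against a
hand-written step-up oracle. Tests are two-sided throughout.

## Synthetic data generator

The generator produces the statistical structure the analyses must detect,
not acoustically realistic screams. A clip is a harmonic carrier (f0 plus
six harmonics at 1/k amplitudes, random phases) multiplied by
(1 + depth · band-limited noise) with additive broadband noise, peak-scaled
to 0.9. Band-limited noise is white noise FFT-masked to the band and
peak-normalized, so the envelope stays positive for depth ≤ 1. Default
per-type parameters plant strong low-band (50–70 Hz) modulation on pain
and fear, strong high-band (140–180 Hz) modulation on anger, and milder
high-band modulation on the non-alarm types, so both roughness bands
separate screams from neutral while modulation depth tracks the alarm
dimension; fundamental frequencies (300–700 Hz) vary by type, speakers
alternate sex with a ∓15 % f0 scale, and instances add ±5 % jitter. These
per-type offsets are free parameters chosen for between-type variety.
Corpus defaults mirror the study conditions: 12 speakers × 7 types × 5
instances (420 clips of 0.8 s at 16 kHz), an affect-burst analog of 16 × 7
× 4 (448), and a selection-sized corpus of 6 × 7 × 2 (84).

Trial logs draw responses from a row-stochastic confusion matrix, miss
trials with a fixed probability (defaults 6.5 % for 7AFC, 1.55 % for 2AFC),
and draw RTs log-normal (right-skewed, two parameters) truncated at the
response window by resampling. Rating tables add Gaussian noise to type
means and clip to the bounded [0, 1] scale. All generators are pure
functions of their arguments including the seed (numpy `default_rng` /
`SeedSequence` spawning).

What the generator does **not** emulate: vocal-tract acoustics, formant
structure, within-type acoustic heterogeneity beyond f0 jitter, per-scream
random effects in ratings, rater idiosyncrasies, sequential effects or
fatigue in behavior, and RT–accuracy coupling. Passing tests therefore
demonstrate that the analysis code recovers planted structure of the
assumed form — not that real screams have that structure.

## Problem sizes

Simulation sizes in the tests and acceptance script are chosen to give
stable statistics at interactive runtimes on a single CPU: permutation
calibration uses 500 permutations × 200 null datasets on small grids;
chance calibration uses 100 label shuffles of a 420 × 88 table; recovery
checks use 40 clips / 100 rating seeds; the end-to-end demo configuration
scales the corpus to 4 speakers × 2 instances with 300 permutations. The
pipeline defaults remain at the full study scale (420 clips, 2000
permutations).

## Known limitations

- The MPS spectral-modulation axis is strongly attenuated above ~1
  cycle/octave at the default 1 ms window; analyses here only use the
  temporal axis, but spectral-modulation results at the 12 cyc/oct bound
  should not be interpreted.
- The permutation map is per-bin; no cluster-level correction over the MPS
  plane is provided.
- d′ pools non-target rows trial-weighted; with strongly unbalanced
  presentation counts an unweighted variant would differ.
- The SVM's hyperparameters are fixed conventions, not tuned values;
  absolute accuracies on real feature tables will depend on them.
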