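# Methods

This note documents the models and numerical choices in `flockstudy`: what
is simulated, what the parameters mean, and where the design was genuinely
open.

## Study design being modelled

A cohort of four observers is trained on two-alternative classification of
square medical-image patches (benign vs malignant histology at 308 × 308
display resolution, or mammogram regions with vs without microcalcification
clusters / masses). Stimuli are split into two sets, A and B; two observers
train on A and are tested on B, two the reverse, with left/right report-button
assignments mirrored within each pair (full counterbalancing). Daily training
sessions comprise 144 trials (histology; 24 exemplars × 6 presentations) or
120 trials (mammograms; 20 exemplars × 6). A rotation phase presents all six
rigid views (0°, 90°, 180°, 270°, horizontal and vertical flips) of each
exemplar once per session. Test sessions interleave the rotated training set
(differentially reinforced) with one nondifferential presentation of each
novel exemplar — 144 + 24 = 168 trials (histology), 120 + 20 = 140
(mammograms). Compression testing presents the full 48-exemplar set three
times (differential) plus 24 compressed probes per day (6 per class at each
of two ratios), cycling through all 96 (exemplar, ratio) pairs every 4 days
for 6 cycles (24 days).

On differential trials only correct choices are reinforced; an incorrect
choice triggers correction trials with the same exemplar until the correct
response occurs. Correction trials are never scored. Nondifferential trials
are reinforced regardless of choice, so testing cannot teach the tested
items; their correct/incorrect designation is for scoring only.

## Stimulus preparation

- **Grayscale reduction** uses Rec. 601 luma weights (0.299, 0.587, 0.114),
  the convention of mainstream image tooling.
- **Single-hue repaint**: the grayscale value becomes the HSV value channel
  at full saturation and a fixed hue (default 290°, approximating the mean
  hue of an H&E stain). The RGB triple for each pixel is constructed
  directly from integer channel arithmetic rather than by rounding a float
  HSV→RGB conversion; together with a small value floor (30/255) for
  non-black pixels this guarantees the repainted hue is within 1° of the
  target for every saturated pixel despite 8-bit quantization. The value
  channel remains a monotone function of input luminance.
- **Equalization** replaces by-hand brightness/contrast matching with a
  single affine intensity remap per class set that equates pooled luminance
  mean and SD (target = midpoint of the two sets). The remap preserves
  within-set luminance rank order; zero-variance sets skip contrast matching
  with a warning.
- **Targeted compression** defines the 1:1 reference as the optimized PNG
  encoding and sweeps the JPEG quality parameter (1–95), selecting the
  quality whose byte ratio is closest to the target (0.07 and 0.04 by
  default). Encoded size is monotone in quality on natural textures, so this
  is a monotone search; unreachable targets raise an error naming the floor.
- **Difficulty-balanced partitioning** minimizes the absolute difference in
  mean panel difficulty between the two class-balanced sets. Up to 20 items
  per class the global optimum is found exactly by a meet-in-the-middle
  search over per-class subset sums (the two per-class choices interact only
  through their sums, so sorting one side's 184 756 sums and binary-searching
  reduces the nominal 3.4 × 10¹⁰ pairings to ~10⁶ operations); larger inputs
  use snake assignment plus pairwise-swap refinement. Ties break on the first
  candidate in lexicographic id order, so results are reproducible.
- **Rotation convention**: 90° means clockwise with the origin at top-left.
  Set membership is unaffected by this choice; it is fixed for
  reproducibility.

## Synthetic observers

No behavioural model is fitted to real animals; the simulator provides the
minimal statistical structure the analyses assume.

- **Evidence**: stimulus *s* on session *t* evokes
  `x ~ Normal(sign(s) · a · (d(t)/2 + offset_s), 1)`, where `sign` is +1 for
  the positive class, `offset_s` is the per-stimulus difficulty (default
  Normal(0, 0.5²); negative values are counter-typical, "conflictive"
  exemplars), and `a` is an attenuation factor (1 for uncompressed stimuli;
  defaults 0.5 and 0.4 for the 15:1 and 27:1 compressions). The observer
  reports positive when `x` exceeds its criterion (default 0, i.e. unbiased).
- **Learning**: `d(t) = dprime_max · (1 − exp(−t/learn_tau))`. Defaults
  `dprime_max = 2.2`, `learn_tau = 4` sessions put the asymptotic accuracy
  near 86% with most of the rise inside the first two weeks of daily
  sessions, the trajectory shape typical of these regimens.
- **Lapses**: with probability `lapse` (default 0.05) the choice is a fair
  coin, capping asymptotic accuracy below 1.
- **Memorization**: each reinforced exposure on a differential trial stores
  the exemplar's label with probability `mem_rate`; at decision time the
  store is consulted with probability `mem_weight`, and a lookup miss is a
  coin flip. The memorizer preset (`mem_weight = 1`, `mem_rate = 0.2`,
  `lapse = 0.35`, `dprime_max = 0`) therefore climbs to ≈ 0.83 on trained
  exemplars while transferring at exactly chance — the rote-learning
  signature. Memory is keyed by exemplar id, not by (exemplar, orientation):
  the rotated views are treated as the same memorized item.
- **Cohort structure**: with `shared_difficulty` (the default) all observers
  see the same per-stimulus offsets, inducing the between-observer error
  correlation that makes vote pooling informative but bounded; with it off,
  offsets are resampled per observer (conditionally independent observers).
  No empirical estimate of this correlation exists for the modelled studies;
  sharing difficulty is an assumption, stated here openly.
- Learning advances with the plan index in the chronology passed to
  `simulate_cohort`; reinforcement on nondifferential trials is never
  reported to the agent, so test days cannot teach test items.

### What the generator does and does not emulate

It reproduces chance-to-asymptote accuracy trajectories, per-image
difficulty correlated with (emulated) human panel accuracy, inter-observer
correlation, compression-graded performance drops, and a memorization regime
with chance transfer. It does not emulate session-to-session drift,
motivational lapse streaks, position habits, stimulus-specific response
biases, or any biologically grounded account of avian vision — so passing
tests certify the pipeline's arithmetic and the statistical machinery, not
fidelity to any particular animal's learning dynamics.

## Analysis stack

- **Accuracy** counts first attempts only; correction records are excluded
  from numerator and denominator.
- **Binomial tests** are exact tail sums (scipy's `binomtest`), one-tailed
  against chance by default; families of comparisons use the Dunn–Šidák
  adjustment `1 − (1 − p)^m`.
- **Flock score** of a stimulus = number of cohort members voting positive,
  an ordinal score on {0..K}; the scoring day must contain exactly one scored
  response per (observer, stimulus) — duplicates and gaps are hard errors
  naming the offenders. The conventional scoring day is the first day of the
  full-set phase, so the score reflects pooling rather than extra training.
- **ROC/AUC**: the empirical curve sweeps "score ≥ c" for c = 0..K+1 (K + 2
  operating points, anchored at (0,0) and (1,1)); no smoothing is applied —
  with a 5-level ordinal score a parametric fit would inject assumptions the
  data cannot check. The trapezoidal area equals the Mann–Whitney statistic
  with half credit for ties (asserted to 10⁻¹² in tests). Variances and
  paired comparisons use the DeLong placement-value method with two-sided
  normal p-values; the implementation is cross-checked in the test suite
  against an independent reference implementation (pROC) and against a
  paired bootstrap. A zero-variance difference (e.g. identical score
  vectors) is reported as a flagged degenerate comparison rather than a
  division by zero.
- **Generalization gap**: familiar-minus-novel accuracy per observer and
  pooled, with Wilson intervals per proportion and the Newcombe score-based
  interval on the difference.
- **Adaptive observing requirement**: the protocol only specifies that the
  pre-choice peck requirement starts at 1 and is raised with poor
  performance up to 6–10. The implementation raises by one peck (cap 10)
  whenever the trailing 3-session mean accuracy falls below 0.65 — a
  deterministic surrogate for the experimenter's judgment.

## Problem sizes in the shipped tests

The test suite exercises the full study arithmetic at its natural sizes
(144/168/120/140-trial sessions, 24-day compression schedule) and scales the
Monte-Carlo work to what the properties require: 500 replicate cohorts of 48
stimuli for the ensemble-gain property, a 15-session × 144-trial × 4-observer
study for likelihood recovery of `dprime_max` (tolerance ± 0.2), an
80-training-day mammogram-mass regimen for the memorization signature, and
10 000-draw checks of the Gaussian-tail accuracy identities. Image fixtures
in tests use sides of 24–64 pixels except where the compression search needs
display-resolution (308 × 308) texture.

## Known limitations

- The equalization remap clips at the 8-bit range; sets whose matched
  intensities would leave [0, 255] will show small residual gaps (warned).
- The JPEG quality sweep assumes monotone size-vs-quality, true for the
  textures at hand but not guaranteed for pathological inputs.
- The memorization channel stores labels without forgetting and without
  orientation specificity; both could matter for fine-grained fits to real
  records.
- `fit_dprime_max` treats the other observer parameters as known; it is a
  one-dimensional likelihood, not a full model fit.
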