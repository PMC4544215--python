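# Methods

`rsvptriage` implements a complete offline analysis chain for single-trial
EEG target detection in rapid serial visual presentation (RSVP) streams,
together with a synthetic-session generator that stands in for recorded data.
This note documents the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic data can and cannot tell you.

## The task being modeled

An observer watches images at 2 Hz and presses a button on rare *targets*.
Two session types are modeled: **TO** (targets only, 1:20 against frequent
*background* distractors, 6 blocks of 120 s) and **TN** (targets plus rare
target-like *non-targets*, each 1:14 against backgrounds, 6 blocks of 134 s).
Rare stimuli are never adjacent and are always followed by at least two
backgrounds (an attentional-blink guard). Block stimulus counts follow from
duration × rate; the fractional rare counts implied by the ratios are rounded
down (TO: 11 targets per 240-stimulus block; TN: 16 targets + 16 non-targets
per 268), and the realized counts are logged rather than asserted.

## Synthetic sessions

**Rare-slot placement.** Admissible rare positions (trailing gap ≥ 2,
pairwise spacing ≥ 3) are sampled *exactly uniformly* via the classic
gap-removal bijection onto unrestricted k-subsets, rather than by sequential
rejection: uniformity is then a theorem, not a property to be audited, and
the same bijection yields the admissible-set count the tests check by
enumeration.

**Evoked responses.** Each stimulus adds a raised-cosine deflection supported
on 300–800 ms (peak 550 ms, half-width 250 ms, both configurable) through a
fixed Gaussian-profile spatial pattern that is maximal (weight 1) at the
midline-parietal "Pz"-role channel. The kernel is normalized so that its
mean over the 400–800 ms P3 window equals 1; a class amplitude of 13.66 µV
(target), 6.61 µV (non-target, midpoint) or −0.44 µV (background) is then
*exactly* the noise-free 400–800 ms epoch mean at Pz — the quantity the
amplitude analysis reports. The 300–800 ms support also fits strictly
between neighbouring onsets' analysis windows at 2 Hz, so the P3 window of
one epoch is never contaminated by the neighbour's kernel.

**Noise.** Per-channel 1/f ("pink") Gaussian noise, unit variance rescaled
to 30 µV, independent across 16 channels at 256 Hz. The scale is the one
generator constant that is calibrated rather than taken from a printed
value: it is set so that default TO sessions run through the full pipeline
land in the high-accuracy regime (mean pooled Az ≈ 0.985) that recorded
sessions of this paradigm reach, and is then frozen. Under the same
conditions TN sessions show non-target misclassification of roughly 40–50%
with low-confidence non-targets — the qualitative fingerprint of
target-like distractors — without any separate tuning.

**Behavior.** Targets elicit presses with probability 0.95 (TO) or 0.85
(TN); non-targets 0.08, backgrounds 0.002. Reaction times are log-normal,
parameterized by the median (514.67 ms TO, 602.82 ms TN; log-sd 0.25):
positive support and right skew are the canonical RT shape, and the median
is the statistic the behavioral analysis reports.

What the generator deliberately omits: ocular/muscle artifacts, spatially
correlated noise, trial-to-trial latency jitter, attentional-blink misses,
and any 2-D scalp geometry. Green tests therefore demonstrate the
correctness of the analysis chain and its behavior under the stated
statistical structure — not robustness to real-EEG nuisance structure,
which recorded data would add on top.

## Preprocessing

Classification stream: order-4 Butterworth band-pass 1–10.66 Hz applied
zero-phase (forward–backward; a config flag restores causal filtering),
then decimation to 32 Hz by integer slicing — the band-pass has already
anti-aliased (10.66 Hz < 16 Hz Nyquist) — then epoching to [0, 1000) ms.
Epoch windows are half-open in samples, `[ceil(start·fs/1000),
ceil(end·fs/1000))` relative to the onset sample, which yields exactly 32
samples per 1-s epoch at 32 Hz; onset times map to samples by rounding
down. Trials extending past the recording are dropped and logged, never
padded (padding biases averages). The ERP stream epochs [−500, 1000) ms at
the acquisition rate and subtracts the per-channel [−500, 0) ms baseline.

## Behavioral scoring

A press within (onset + 200 ms, onset + 1000 ms] of a rare stimulus is a hit
(target) or false positive (non-target); unattributable presses are
background false positives. A press eligible for several rare stimuli —
impossible under the generator's spacing, possible for arbitrary input — is
attributed to the most recent uncredited one (shorter implied RT). HR and
FPR use half-count edge correction (1/(2N)) before the probit transform;
d′ = Z(HR) − Z(FPR), with FPR pooled over non-target classes by default and
per-class rates also emitted.

## xDAWN + BLDA

xDAWN is implemented from its algebraic model: Toeplitz designs D1 (target
onsets) and D2 (all onsets), joint least-squares estimation of the target
response A1 and common response A2, and spatial filters as the top
generalized eigenvectors of (Â1ᵀD1ᵀD1Â1, XᵀX), ranked by their SSNR
Rayleigh quotients. Choices the formulation leaves open:

- **N1 = N2 = 32 samples** (one epoch length at 32 Hz) — matches the
  feature dimension and the natural response duration.
- **X assembly inside the CV pipeline** stacks the training-fold epochs
  (one onset per 32-sample block). The module-level functions are
  timeline-agnostic and accept true continuous recordings equally.
- **Conditioning:** XᵀX gets a trace-scaled ridge (λ = 1e-9); a
  rank-deficient [D1; D2] falls back to the pseudoinverse with a warning.
- **Normalization:** filters have unit norm in the XᵀX metric, so the eight
  filtered time courses share a scale. Features are the 8 × 32 = 256
  concatenated time courses, filter-major.

BLDA is Bayesian linear regression on class-size-balanced targets (+N/N₊,
−N/N₋ — this is what absorbs the 1:20 imbalance without resampling), with
an isotropic prior of precision α over the augmented weights and noise
precision β, both set by MacKay's evidence fixed point (max 100 iterations,
tolerance 1e-6 on |Δlog α| + |Δlog β|; convergence typically takes < 10).
One deliberate simplification: the bias is regularized together with the
weights, so freezing (α, β) reproduces the ridge closed form exactly — the
oracle the tests use. No feature standardization by default (a flag
exists); the xDAWN metric normalization already fixes the scale.

## Confidence and evaluation

The threshold κ maximizes TPR − FPR over midpoints of adjacent distinct
scores; J is compared in exact integer arithmetic and ties break toward the
higher cut (fewer predicted targets — conservative for triage). By default
κ is placed on the held-out 10% threshold slice, the purpose of the nested
design; `threshold_on="train"` switches to training scores. Confidence is
the distance from κ rescaled by the *training-set* score extrema, branch-wise
above/below κ, clipped to [0, 1] for out-of-range validation scores; κ is
clipped strictly inside the training extrema when the threshold slice puts
it outside.

Cross-validation is contiguous nested 10-fold: validation = slice k,
threshold = slice (k+1) mod 10, train = the rest; slice boundaries are
⌊i·n/10⌋, so sizes differ by at most one and the scheme is deterministic.
Az is the trapezoidal ROC area (ties half-weighted), computed per fold and
on validation scores pooled across folds. Percentile thresholds (0–90% in
10% steps) are empirical order statistics over pooled confidences; trials
strictly below the threshold form the low-confidence subset, and boundary
ties stay high-confidence.

The mitigation simulation replaces low-confidence predictions with the true
labels (a perfectly accurate manual labeler) and recomputes metrics over
*all* trials; for Az the manual trials take max(score)+ε / min(score)−ε so
they sort outside the retained trials without disturbing their ordering.
Labeling-time overhead is 100 · (manual fraction × seconds per manual
label) / (seconds per RSVP image); at 30%, 1 s and 0.5 s this is 60%.

## Problem sizes

Defaults everywhere are one session = 6 blocks (1,440 trials TO, 1,608 TN),
16 channels at 256 Hz. The acceptance script averages pooled Az over five
TO sessions (~7,200 validated trials); the test suite's Monte-Carlo checks
use one to five sessions or reduced block counts per test, sizes chosen so
each check's sampling error is small against its assertion margin.

## Known limitations

- Single-subject scope: group statistics (Wilcoxon, ANOVA, FDR) are out of
  scope; the per-session tables feed any standard package.
- The synthetic spatial pattern is rank-1, which flatters spatial
  filtering; with 16 independent-noise channels xDAWN recovers it easily.
- EDF/BDF export is not provided (no EDF writer among the dependencies);
  the npz + JSON + TSV container and loader are the supported interchange.
- Confidence is the paper-style distance-to-boundary measure only; density-
  or ensemble-based confidence is explicitly out of scope.
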