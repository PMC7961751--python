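# Methods

## The detection problem

Four physiological channels — heart rate (HR, beats per minute), breath
rate (BR, breath cycles per minute), skin conductance (SC, microsiemens)
and skin temperature (ST, °C) — are recorded at 10 Hz while a subject
works through learning tasks in 9-minute sessions (2 min rest, 5 min
activity, 2 min rest). Experts mark the instants of *concentration
peaks*. The question is whether those windows of engaged concentration
can be recognised from the signals alone, and whether the mapping from
concentration to physiology is shared across people or idiosyncratic.

## Sample extraction

Concentration is treated as sustained over a short span around each
labelled peak, so a *concentrated sample* is the 6 s excerpt centred on
the peak: the frames in `[t − 3 s, t + 3 s)` with the peak snapped to the
nearest frame index, i.e. a `C × 60` matrix at 10 Hz (4 × 60 with all
channels). Half-open frame windows make the 60-measurement contract
exact; windows that leave the recording or touch an invalidated artifact
span are skipped.

*Non-concentrated samples* are 6 s slots packed greedily left-to-right
after discarding the first second of the session, under three
constraints: every frame of a slot at least 120 s from every
concentration peak (nearest-point distance, the stricter reading),
consecutive slots at least 6 s apart, and no overlap with invalid spans.
Greedy earliest-start packing of equal-length slots is provably maximal;
the test suite confirms it against an exhaustive dynamic program.

Artifact filtering precedes extraction: frames with SC ≤ 0 (electrode
contact loss) or HR outside [25, 240] BPM (pulse-sensor glitches) are
linearly interpolated when the run lasts ≤ 1 s, and marked invalid
otherwise. The thresholds and the 1 s gap policy are configurable
defaults — physiological plausibility bounds, not measured constants.

## The one-class HMM score

For each experiment a hidden Markov model θ with K = 3 states and
per-state diagonal-Gaussian emissions is fitted by Baum–Welch to
*positive* windows only, and every test window X is scored by the total
sequence likelihood log p(X | θ) (forward algorithm). Higher scores mean
"more like the training class"; no negative windows are ever used for
training.

Choices that matter, and why:

* **K = 3 states, diagonal Gaussians.** Training sets can be as small as
  five 60-frame windows; a three-state diagonal model keeps the
  parameter count (K−1 + K(K−1) + 2KD ≈ 32 for D = 4) below the frame
  count of even the smallest training set. K is configurable.
* **Standardisation.** Channels differ by orders of magnitude (70 BPM vs
  5 µS), so each fit z-scores per channel using *training-set* statistics
  and applies the same constants to its test windows. Test windows far
  from the training distribution therefore score very low — which is the
  point of a one-class score.
* **Initialisation.** State means start at evenly spaced quantiles of the
  pooled training frames plus a small seeded perturbation; initial and
  transition distributions start uniform. One EM run per fit (restarts
  configurable): the outer iteration loop dominates runtime and already
  averages over initialisations.
* **Numerics.** EM uses the per-step-scaled forward/backward recursion;
  *scoring* uses a log-domain forward instead, because a window scored
  under another subject's model can sit hundreds of standard deviations
  from every state and underflow any scaled recursion. Emission
  variances are floored at 1e−6 so near-constant windows cannot collapse
  a state; the training log-likelihood trace is non-decreasing to 1e−8.

## Evaluation

The iterated hold-out scheme draws, per iteration, a random 75/25 split
of S+ (⌊0.75·n⌋ training positives, minimum 2), fits θ on the training
positives, and scores the held-out positives together with **all** of
S−. Scores from all iterations (12,500 by default) are pooled into one
ROC curve. Pooling raw log-likelihoods across iterations is legitimate
here because every window has the same length (60 frames), so scores
share a scale; a per-iteration-ROC averaging mode exists for sensitivity
analysis. Per-iteration RNG substreams derive from `(seed, iteration)`,
making a run bit-reproducible.

AUC is the midrank Mann–Whitney statistic (ties count ½), which equals
the trapezoidal area under the tie-grouped ROC polygon exactly. EER is
read off the polygon by linear interpolation where the false-positive
rate equals the false-negative rate.

The three experiments, each repeated per subject u:

1. **Intra-subject detection** — S+ = u's concentrated, S− = u's
   non-concentrated windows.
2. **Subject identification** — S+ = u's concentrated, S− = everyone
   else's concentrated windows.
3. **Inter-subject transfer** — a single fit, no iteration loop. The
   default direction trains on the pooled concentrated windows of all
   *other* subjects and tests on u's positives and negatives; a flag
   selects the reverse direction (train on u, test on the others), since
   both designs are defensible and differ only in which side is held
   out.

The **fusion sweep** repeats experiments 1 and 2 for every nonempty
subset of the channel set — 2⁴ − 1 = 15 subsets for four channels —
in deterministic order (by subset size, then HR, BR, SC, ST), reporting
per-subject AUC/EER and averages per subset. The transfer experiment is
excluded from the sweep by design.

## The synthetic cohort generator

No recordings are distributed with this package, so every pipeline stage
is exercised on synthetic cohorts with the statistical structure the
analysis assumes. Per channel, a session is

    baseline(subject) + AR(1) noise + event-locked deflection,

with defaults:

| channel | baseline anchor | between-subject sd | AR(1) innovation sd | deflection |
|---------|-----------------|--------------------|---------------------|------------|
| HR | 70 BPM | 8 | 0.8 | +5 |
| BR | 15 BCPM | 2 | 0.5 | +2 |
| SC | 5 µS | 1.5 | 0.08 | +0.8 |
| ST | 33 °C | 0.8 | 0.02 | −0.5 |

The AR(1) coefficient is 0.95 at 10 Hz (≈ 2 s correlation time,
emulating slow physiological drift). Anchors are conventional resting
physiology; the deflection signs follow sympathetic arousal (faster
heart/breath rate, more sweat-gland activity, peripheral
vasoconstriction cooling the skin). `subject_scale` multiplies the
between-subject spread of baselines and of the per-channel deflection
shape; `state_scale` multiplies the deflection itself. Cohorts default
to 4 subjects × 4 sessions of 540 s, with 2–7 events per session placed
≥ 9 s apart in a 120 s cluster at mid-activity — so the rest blocks stay
more than two minutes from every peak and remain eligible for negative
slots, and per-subject positive counts land in a realistic 8–28 range.

The deflection is a raised cosine with half-width `ramp_s = 4.5 s`: it
peaks at exactly `baseline + delta`, integrates to `delta × ramp_s`, and
*outlasts* the 6 s excerpt window, reflecting that the window samples a
sustained state rather than containing all of it. Concentration also
**steadies** the signals: the AR(1) innovation sd is multiplied by
`exp(−0.7 · state_scale · envelope(t))`, emulating suppressed
heart-rate variability and stiller posture during focus. This
second-order effect is essential, not cosmetic: a one-class likelihood
score cannot penalise a flat window whose values lie inside the span of
the trained bump trajectory, so a pure mean-shift deflection caps
intra-subject AUC near chance at *any* amplitude. With the variance
effect, the positive-trained model's tight state variances make
full-variance negatives unlikely, and intra-subject AUC approaches 1 as
`state_scale` grows — the behaviour the real study reports for real
signals, whose concentration windows presumably differ in dynamics, not
just level.

What the generator does **not** emulate: cardiorespiratory coupling,
circadian/within-session trends, movement artifacts beyond the validity
ranges, labelling noise in peak times, or any biophysical waveform
shape. Passing tests on these cohorts demonstrate that the pipeline
recovers the structure it assumes; they say nothing about how strongly
real concentration expresses itself in real signals.

## Problem sizes and determinism

Experiment-level tests and the acceptance script run the hold-out scheme
at 500 iterations rather than the full 12,500: the pooled ROC over
500 × (held-out + |S−|) scores is already stable to well under the
tolerances tested, and the scheme is embarrassingly repeatable (any
iteration count reproduces exactly from the master seed). The three
regimes evaluated are: strong state effects (`state_scale = 3`) for
intra-subject detection; strong subject effects (`subject_scale = 2`)
for subject identification; and subject effects dominating state effects
(`subject_scale = 2, state_scale = 0.25`) for the inter-subject
transfer, whose AUC is assessed as the average over 8 replicate cohorts
(32 single fits). Replication matters there: single-subject transfer
AUCs are intrinsically volatile — the foreign model's geometry can order
one subject's classes almost deterministically in either direction — and
even one 4-subject cohort's mean has a Monte-Carlo sd of ~0.14 around
chance, while the 8-cohort mean (~0.05) makes "near chance" a statement
about the effect rather than the seed. Near-chance transfer is in any
case a cohort-level claim, not a per-subject one.

Null regimes (`state_scale = 0`, or `subject_scale = 0` with a shared
noise law) are asserted at AUC = 0.5 ± 0.1 on the cohort mean, whose
Monte-Carlo sd (~0.04) makes the band meaningful; a per-subject band at
a single seed would be dominated by the ~0.08 sd of one pooled ROC.

## Known limitations

* The generator's effect sizes are free parameters; only qualitative
  regimes (strong / weak / null) are meaningful, not absolute AUCs.
* Equal-length sequences are assumed throughout scoring (they are, by
  construction of the windows); `fit` truncates to the shortest sequence
  if handed ragged input.
* EM is a local optimiser run once per fit; with K = 3 on five windows,
  different seeds can land on different local optima. The iterated
  scheme averages over this by design.
* The EER interpolation assumes the ROC polygon crosses FPR = FNR once,
  which monotonicity of the curve guarantees.
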