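# Methods

## Data model and conventions

A *session* is one dyad's annotated recording: four trials crossing model
visibility (visible/hidden) with talking (allowed/forbidden), each
contributing its first annotated minute (default 60 s; the time origin of
every trial is the start of its annotated segment). Each trial carries one
categorical gaze stream per participant — every sample assigned to exactly
one of five AOIs (blocks, build, model, face, none) — and an episode table
of actions, gestures and utterances with onsets/offsets in seconds.

Conventions that downstream results depend on:

- **Half-open episodes** `[onset, offset)`: a sample exactly at the offset
  is outside, so abutting episodes never share a sample and each retains
  its own onset.
- **Speech** exists only in trials where talking was allowed; in the other
  trials speech-conditioned quantities are *missing*, never zero, because
  speech was never annotated there.
- **Participants are unordered** within a dyad; "the other person" is
  resolved per analysis call, never stored.

## Fusion

A 60 Hz timeline `t_k = k/60` spans each trial (3600 samples per 60-s
trial). Every timeline sample takes the AOI of the temporally nearest raw
gaze sample; at the nominal raw rate of 30 Hz the offset is at most
16.7 ms and is recorded per sample. A timeline point equidistant from two
raw samples takes the **earlier** one — deterministic and causality-leaning;
either convention is defensible, this one is fixed and tested. Gaze
coverage shorter than the annotated minute truncates the timeline with a
warning; fusion never imputes labels.

## Onset-locked curves

The onset of an episode is its first fused sample. For each event type the
curves report, at each grid offset τ ∈ {−180, …, +180}/60 s, the mean over
pooled instances of the indicator that the observer fixates a given AOI at
onset + τ. Pooling is across all dyads and both participants (not a mean
of per-participant means); instances whose window crosses a trial boundary
contribute only in-bounds offsets, so the per-τ instance count varies and
is reported. The default CI is the normal approximation
`p ± z·sqrt(p(1−p)/n)` clipped to [0, 1] — cheap, monotone, and exact in
the degenerate p ∈ {0, 1} cases; Wilson intervals are available via
`ci_method="wilson"` for small-n curves. These intervals treat instances as
independent and ignore within-participant clustering; they describe
instance-level sampling noise, nothing more.

## Episode-conditional dwell

Relative dwell on a target AOI during category c is
`#{samples: state = c AND gaze = target} / #{samples: state = c}` per
trial; the per-participant value is the unweighted mean over trials with a
nonzero denominator (a duration-weighted variant is available via
`weight_by_duration=True`). Per trial the category decomposition is exactly
conservative: Σ_c (samples in c) × (dwell in c) equals the total samples on
the target AOI, which the tests assert verbatim.

## Harrell–Davis estimator and shift function

`HD(x, q) = Σᵢ wᵢ x₍ᵢ₎` with `wᵢ = I_B(i/n; a, b) − I_B((i−1)/n; a, b)`,
`a = (n+1)q`, `b = (n+1)(1−q)`. The shift function compares two dwell
distributions at the deciles q = 0.1…0.9: differences `HD(b) − HD(a)` with
percentile-bootstrap CIs from `nboot = 2000` independent resamples per
group at `alpha = 0.05`. The independent-groups design is deliberate:
dwell during a rare gesture type is missing for participants who never made
one, so pairing is impossible and missing values are dropped listwise per
group. Groups below n = 10 warn; below n = 5 the routine refuses.

**Known limitation.** The simple per-decile percentile interval undercovers
at the extreme deciles for small groups: at n = 21 per group the measured
coverage of the nominal 95% interval is ≈ 0.92 at deciles 0.1 and 0.9
(≈ 0.95–0.96 at the central deciles) — the acceptance suite computes this
and the result is reproduced by an independent from-scratch implementation
of the same procedure. Simultaneous (FWER-controlling) critical values
would repair the extremes and are out of scope in v1.

## Gaze-inference models and benchmark

Six models: predictor stream ∈ {action, gesture, speech} × source ∈
{own, other}. Training pools, per event type, the onset-locked conditional
probabilities over the training dyads on the ±3 s / 60 Hz grid (the same
counting code as the timelock curves). Inference labels each fused gaze
sample by averaging, over all predictor onsets within a closed ±3 s window,
the type-specific probability vectors at the sample's grid offset from each
onset, then taking the argmax. Deterministic choices:

- **Fallback**: samples with no onset in the window get the training-modal
  AOI — identical to the benchmark model's constant prediction, so with no
  onsets at all every model collapses exactly onto the benchmark (tested).
- **Tie-break** for argmax/modal AOI: fixed priority model > build >
  blocks > face > none (training-frequency order in this task).
- Conditional tables are **per event type** (grab and place have distinct
  curves); a pooled-stream variant sits behind `pooled=True`.
- τ bins with zero training instances, and event types absent from
  training, substitute the training marginal AOI distribution.
- Onsets never cross trial boundaries; speech models draw onsets only from
  talking trials and therefore emit the fallback throughout no-talk trials.
- Training instances are pooled raw (not weighted per participant),
  consistent with the curve pooling above.

The benchmark emits the training-modal AOI everywhere; its held-out score
is therefore exactly the held-out pair's proportion of gaze on that AOI
(asserted exactly in the tests). Evaluation is leave-one-pair-out:
per-trial scores pool both participants' samples; pair means over the four
trials and the grand mean over pairs are unweighted.

The model surface follows the fitted-model idiom: `GazeInferenceModel`
(data + specification) → `fit()` → `GazeInferenceResults` (scores,
dispersion across pairs, `summary()`), with `loocv_evaluate` as the
functional shorthand.

## Synthetic dyad generator

The generator's defaults are the study conditions: 19 dyads, 60-s trials
covering the 2×2 design in shuffled order, and per-minute rates grab 9.25,
place 8.50, remove 1.00, drop 1.12, point 1.62, ask 0.25, instruct 0.25;
baseline AOI marginals blocks 0.11, build 0.25, model 0.47, face 0.005,
none 0.165; speech occupying ≈ 0.24 of talking-trial time in ≈ 12
utterances/min (mean utterance 1.2 s, mean gap 3.8 s). Episode durations
are log-normal with medians derived from time-share ÷ frequency (grab
1.4 s, place 2.3 s, remove 0.60 s, drop 0.55 s, point 1.48 s; ask/instruct
1.0 s) and a common log-sd of 0.4.

Actions form an alternating grab→place renewal chain: idle gap
(exponential), grab, handling gap (exponential, mean 0.9 s), place — with
each place present with probability `place_rate/grab_rate`, so unequal
grab/place rates are honoured and `place_rate = 0` gives a pure grab
renewal process. The mean cycle is calibrated to `60/grab_rate` and the
chain is burnt in for `max(30, 5·cycle)` seconds before t = 0, so the
expected grab count over the annotated minute equals the configured rate
(verified by Monte Carlo in the tests). Configurations whose durations
cannot fit the cycle raise a configuration error. Remove/drop and the
three gesture types are Poisson processes thinned against whatever already
occupies their stream; speech is an alternating quiet/talking renewal
process on talking trials.

Gaze is drawn per 30 Hz sample from
`softmax(log π + Σₖ Aₖ exp(−(t − oₖ − cₖ)²/2wₖ²))`, kernels additive over
concurrent events from the configured source (own/other). Sampling is
i.i.d. given the event context — deliberately, so closed-form checks are
exact and the generating probability matrix (`gaze_probabilities`) is an
exact oracle for estimator validation. An optional first-order sticky
variant (`stickiness` = probability of repeating the previous sample)
exists for robustness checks. Default kernels reproduce the qualitative
ordering seen in this kind of task: strong own-action coupling
(grab→blocks, place→build at +2 log-odds), weaker own-gesture coupling
(point→model, ask/instruct→face), and weak cross-person kernels
(+0.75…1 log-odds).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: gaze dwell persistence (i.i.d. sampling gives
far more AOI switches per minute than human fixation behavior), individual
differences in coupling strength or timing, coordination between the two
partners' event processes (partners are generated independently), task
progress, and any continuous gaze kinematics. Recovery results on
synthetic data validate the estimators, not the psychology.

## Numerical choices

- Nearest-gaze ties compare distances with a 1e-9 s tolerance so that
  equidistance is detected reliably in float arithmetic regardless of
  absolute time.
- Episode membership and onset snapping use a 1e-9 s guard when locating
  grid samples.
- Written CSVs carry six decimals; read∘write is an identity to 1e-6 s on
  times and exact on every label (property-tested), and identical seeds
  give byte-identical files.
- All randomness flows from `numpy.random.Generator` objects seeded from a
  single configured seed (per-dyad child seeds via `SeedSequence.spawn`).

## Problem sizes used in validation

The stochastic validation checks run at sizes chosen to make their
Monte-Carlo error small relative to the asserted effects: 200 simulated
trials (≈ 3700 grab instances) for onset-locked curve recovery against the
generating softmax oracle; 20 dyads for the null-coupling (all models
within ±2 points of the benchmark) and positive-coupling (own-action model
≥ 5 points above it) checks; 1000 replications × 2000 bootstrap resamples
for shift-function coverage; 100 random 10-s fixtures for exact agreement
between the vectorized labeler and a scalar reference.
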