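# dyadgaze

Analysis of gaze–action, gaze–gesture and gaze–speech coupling in dyadic
collaboration, for researchers working with wearable eye tracking and
behavioral annotation of face-to-face interaction.

When two people build something together, where each of them looks is
tightly bound to what their hands are doing — gaze visits the blocks area
around the moment of a grab, the build area around a place — and more
loosely bound to gestures, speech, and the partner's behavior. `dyadgaze`
implements the full analysis chain for quantifying these couplings from
categorical gaze data (five areas of interest: blocks, build, model, face,
none) and interval annotations of manual actions (grab, place, remove,
drop), gestures (point, ask, instruct) and speech (talking):

1. **Fusion** — raw 30 Hz gaze AOI labels and episode annotations are
   combined onto a common 60 Hz timeline (nearest-neighbour gaze
   assignment, max offset 16.7 ms; half-open episode membership).
2. **Onset-locked curves** — the proportion of looks `P(AOI | τ)` for
   τ ∈ [−3, +3] s around event onsets, pooled over all instances, with 95%
   CI bands.
3. **Episode-conditional dwell** — relative total dwell time on a target
   AOI while a behavior category is ongoing, per trial, averaged per
   participant (missing — not zero — when a category never occurs).
4. **Shift functions** — Harrell–Davis decile estimates
   `HD(x, q) = Σᵢ wᵢ x₍ᵢ₎` with Beta((n+1)q, (n+1)(1−q)) weights, and
   per-decile differences between two dwell distributions with
   percentile-bootstrap CIs (independent groups, so participants missing
   from one condition are simply dropped from that group).
5. **Gaze inference** — six conditional-probability models (own/other ×
   action/gesture/speech): train `P(AOI | event type, τ)` on all dyads but
   one, label every held-out gaze sample by averaging the probability
   vectors of all onsets within ±3 s and taking the argmax, falling back to
   the training-modal AOI when no onset is near; scored as proportion
   correct against a majority-class benchmark under leave-one-pair-out
   cross-validation.
6. **Synthetic dyads** — a generator with renewal-process events and known
   Gaussian log-odds coupling kernels
   `logitₐ(t) = log πₐ + Σₖ Aₖ exp(−(t − oₖ − cₖ)²/2wₖ²)`,
   so every stage can be validated against ground truth without any
   recorded data.

## Worked example

```python
import dyadgaze as dg

cfg = dg.default_config(n_dyads=6, seed=42)
sessions = dg.generate_dataset(cfg)
fused = [dg.fuse_session(s) for s in sessions]

model = dg.GazeInferenceModel(fused, dg.ModelSpec("action", "own"))
res = model.fit()
print(res.summary())

flat = [ft for sess in fused for ft in sess]
onsets = dg.extract_onsets(flat, "action", "grab", "own")
peak = dg.peak_summary(dg.timelock_proportions(onsets), "blocks")
print(f"grab->blocks: start {peak.start:.3f}, "
      f"peak {peak.max:.3f} at {peak.max_tau_s:+.3f} s ({len(onsets)} onsets)")
```

prints

```
Gaze inference: leave-one-pair-out cross-validation
===================================================
predictor stream : action
predictor source : own
window           : +/- 3 s at 60 Hz
pairs            : 6

                    accuracy      SE
model                  0.444   0.002
benchmark              0.371   0.004
advantage              0.073

grab->blocks: start 0.118, peak 0.518 at +0.067 s (446 onsets)
```

Reading: under the default synthetic coupling, knowing when one's own
manual actions occur lets the model label 44.4% of gaze samples correctly
versus 37.1% for always guessing the most-fixated AOI — a 7.3-point gain.
The onset-locked curve shows the probability of looking at the blocks area
rising from its baseline (~0.12 three seconds before a grab) to a peak of
0.52 essentially at grab onset.

The same stages are available from the shell:

```sh
dyadgaze simulate --seed 1 --out data/
dyadgaze timelock --in data/ --stream action --type grab --out grab.csv
dyadgaze infer --in data/ --predictor action --source own --out results/
dyadgaze run --seed 1 --out artifacts/   # full pipeline + figures
```

## Layout

- `src/dyadgaze/data_model.py` — domain types, tidy CSV I/O, validation,
  descriptive statistics
- `src/dyadgaze/synthetic.py` — the dyad generator and coupling kernels
- `src/dyadgaze/fusion.py` — the 60 Hz combined data structure
- `src/dyadgaze/timelock.py` — onset-locked proportion-of-looks curves
- `src/dyadgaze/episode_stats.py` — episode-conditional dwell
- `src/dyadgaze/robust_stats.py` — Harrell–Davis estimator, shift function
- `src/dyadgaze/inference.py` — gaze-inference models, benchmark, LOOCV
- `src/dyadgaze/pipeline.py`, `report.py`, `cli.py` — orchestration,
  figures, command line

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
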