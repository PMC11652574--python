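"""Shared fixtures and independent reference implementations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dyadgaze as dg
from dyadgaze.data_model import AOI_LABELS, AOI_PRIORITY, EPISODE_COLUMNS, EVENT_LABELS


# ---------------------------------------------------------------------------
# Independent brute-force reference for the inference labeler.
# Deliberately scalar: explicit loops over samples and onsets.
# ---------------------------------------------------------------------------

def brute_force_infer(table, fused, participant, spec):
    """Per-sample scalar reference for :func:`dyadgaze.infer_gaze`."""
    actor = participant if spec.source == "own" else fused.partner_of(participant)
    ep = fused.episodes
    onsets = []
    for _, row in ep.iterrows():
        if row.stream != spec.stream or row.participant != actor:
            continue
        idx = None
        for k in range(fused.n_samples):
            if fused.time_s[k] >= row.onset_s - 1e-9:
                if fused.time_s[k] < row.offset_s - 1e-9:
                    idx = k
                break
        if idx is not None:
            onsets.append((row.label, idx))

    half = spec.n_steps
    out = []
    for i in range(fused.n_samples):
        vecs = []
        for label, idx in onsets:
            d = i - idx
            if -half <= d <= half:
                vecs.append(table.probs[label][d + half])
        if not vecs:
            out.append(table.fallback_aoi)
            continue
        avg = [0.0] * len(AOI_LABELS)
        for v in vecs:
            for j in range(len(AOI_LABELS)):
                avg[j] += v[j] / len(vecs)
        best, best_val = None, -1.0
        for a in AOI_PRIORITY:
            val = avg[AOI_LABELS.index(a)]
            if val > best_val:
                best, best_val = a, val
        out.append(best)
    return np.array(out, dtype=object)


# ---------------------------------------------------------------------------
# Fixture builders
# ---------------------------------------------------------------------------

def make_trial(
    dyad_id="d01",
    trial_index=1,
    duration_s=10.0,
    talking="forbidden",
    visibility="visible",
    aoi_by_participant=None,
    episodes=None,
    rate_hz=30.0,
    participants=("p1", "p2"),
):
    """Hand-built trial with constant or supplied gaze label sequences."""
    n = int(round(duration_s * rate_hz))
    times = np.arange(n) / rate_hz
    gaze = {}
    for p in participants:
        labels = (
            aoi_by_participant[p]
            if aoi_by_participant and p in aoi_by_participant
            else np.full(n, "model", dtype=object)
        )
        gaze[p] = dg.GazeStream(participant=p, rate_hz=rate_hz, time_s=times, aoi=labels)
    ep = (
        pd.DataFrame(episodes, columns=EPISODE_COLUMNS)
        if episodes
        else pd.DataFrame(columns=EPISODE_COLUMNS)
    )
    return dg.Trial(
        dyad_id=dyad_id,
        trial_index=trial_index,
        model_visibility=visibility,
        talking=talking,
        duration_s=duration_s,
        gaze=gaze,
        episodes=ep,
    )


def make_session(
    dyad_id="d01",
    duration_s=10.0,
    episodes_per_trial=None,
    aoi=None,
    participants=("p1", "p2"),
):
    """A minimal valid session covering the four conditions."""
    conditions = [
        ("visible", "forbidden"),
        ("visible", "allowed"),
        ("hidden", "forbidden"),
        ("hidden", "allowed"),
    ]
    trials = []
    for i, (vis, talk) in enumerate(conditions, start=1):
        eps = episodes_per_trial[i - 1] if episodes_per_trial else None
        trials.append(
            make_trial(
                dyad_id=dyad_id,
                trial_index=i,
                duration_s=duration_s,
                talking=talk,
                visibility=vis,
                aoi_by_participant=aoi,
                episodes=eps,
                participants=participants,
            )
        )
    return dg.Session(dyad_id=dyad_id, trials=trials)


def random_fused_trial(rng, duration_s=10.0, n_events=6, dyad_id="d01", trial_index=1):
    """A fused trial with random gaze and random non-overlapping episodes."""
    aoi = {
        p: np.array(AOI_LABELS, dtype=object)[
            rng.integers(0, len(AOI_LABELS), int(duration_s * 30))
        ]
        for p in ("p1", "p2")
    }
    rows = []
    for p in ("p1", "p2"):
        for stream in ("action", "gesture", "speech"):
            t = 0.0
            for _ in range(rng.integers(0, n_events + 1)):
                t += rng.uniform(0.1, 2.5)
                dur = rng.uniform(0.1, 1.5)
                if t + 0.02 >= duration_s:
                    break
                label = rng.choice(EVENT_LABELS[stream])
                rows.append((p, stream, label, round(t, 3), round(min(t + dur, duration_s), 3)))
                t += dur
    talking = "allowed" if any(r[1] == "speech" for r in rows) else "forbidden"
    trial = make_trial(
        dyad_id=dyad_id,
        trial_index=trial_index,
        duration_s=duration_s,
        talking=talking,
        aoi_by_participant=aoi,
        episodes=rows or None,
    )
    return dg.fuse_trial(trial)


def random_table(rng, spec):
    """A random normalized conditional-probability table."""
    probs = {}
    counts = {}
    for t in EVENT_LABELS[spec.stream]:
        p = rng.random((2 * spec.n_steps + 1, len(AOI_LABELS))) + 0.05
        p /= p.sum(axis=1, keepdims=True)
        probs[t] = p
        counts[t] = np.full(2 * spec.n_steps + 1, 10)
    marginal = rng.random(len(AOI_LABELS)) + 0.05
    marginal /= marginal.sum()
    from dyadgaze.inference import CondProbTable, _argmax_priority

    return CondProbTable(
        spec=spec,
        probs=probs,
        counts=counts,
        marginal=marginal,
        fallback_aoi=AOI_LABELS[int(_argmax_priority(marginal[None, :])[0])],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Five synthetic dyads with default coupling, 30-s trials."""
    cfg = dg.default_config(n_dyads=5, duration_s=30.0, seed=11)
    return dg.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fused(small_dataset):
    return [dg.fuse_session(s) for s in small_dataset]
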