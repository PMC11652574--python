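"""Reconstruction of the combined 60 Hz categorical data structure.

Raw gaze is recorded at a nominal 30 Hz while actions, gestures and speech
are annotated as onset/offset intervals. Fusion builds a common 60 Hz
timeline per trial, assigns each timeline sample the temporally nearest raw
gaze AOI label (maximum offset 16.7 ms for 30 Hz input), and marks for each
sample whether it falls inside an action, gesture or speech episode — if
not, the no-episode state ("none", or "quiet" for speech) is assigned.

Ties when a timeline point is equidistant from two raw gaze samples resolve
to the earlier raw sample (deterministic, causality-leaning). Episode
membership uses half-open intervals ``[onset, offset)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import NO_EVENT, STREAMS, GazeStream, Trial
from .errors import GapError

FUSED_RATE_HZ = 60.0
#: Maximum tolerated distance between a fused sample and its source gaze
#: sample for nominally 30 Hz input: half the 30 Hz period, i.e. 16.7 ms.
MAX_OFFSET_S = 1.0 / 60.0


def build_timeline(duration_s: float) -> np.ndarray:
    """60 Hz timestamps t_k = k/60 for k = 0..ceil(duration*60)-1.

    All timestamps lie strictly within ``[0, duration_s)``; a 60-s trial
    yields exactly 3600 samples.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = math.ceil(duration_s * FUSED_RATE_HZ - 1e-9)
    return np.arange(n) / FUSED_RATE_HZ


def nearest_indices(raw_time_s: np.ndarray, timeline: np.ndarray) -> np.ndarray:
    """Index of the raw sample temporally nearest each timeline point.

    Equidistant ties resolve to the earlier raw sample.
    """
    raw_time_s = np.asarray(raw_time_s, dtype=float)
    right = np.searchsorted(raw_time_s, timeline, side="left")
    right = np.clip(right, 0, len(raw_time_s) - 1)
    left = np.clip(right - 1, 0, len(raw_time_s) - 1)
    d_left = np.abs(timeline - raw_time_s[left])
    d_right = np.abs(raw_time_s[right] - timeline)
    # earlier sample wins on ties (to float tolerance), except when the
    # timeline point coincides with the right sample
    tol = 1e-9
    use_left = (d_left <= d_right + tol) & (d_right > tol) & (left < right)
    idx = np.where(use_left, left, right)
    return idx


def assign_nearest_gaze(
    gaze: GazeStream, timeline: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each timeline sample the AOI of the nearest raw gaze sample.

    Returns ``(labels, offsets)`` where ``offsets[k]`` is the signed time
    difference (timeline minus source gaze time) in seconds. A timeline
    point farther than one raw sampling period from every gaze sample is a
    coverage gap and raises :class:`GapError` naming the interval.
    """
    period = 1.0 / gaze.rate_hz
    idx = nearest_indices(gaze.time_s, timeline)
    offsets = timeline - gaze.time_s[idx]
    gap = np.abs(offsets) > period + 1e-9
    if gap.any():
        bad = timeline[gap]
        raise GapError(
            f"gaze coverage gap: timeline points in [{bad.min():.4f}, "
            f"{bad.max():.4f}] s are farther than one raw period "
            f"({period:.4f} s) from any gaze sample"
        )
    return gaze.aoi[idx], offsets


def assign_episode_labels(
    episodes: pd.DataFrame, stream: str, participant: str, timeline: np.ndarray
) -> np.ndarray:
    """Label each timeline sample with its episode category or the no-episode state.

    Membership is half-open: a sample exactly at ``offset_s`` is outside.
    """
    if stream not in STREAMS:
        raise ValueError(f"unknown stream {stream!r}")
    labels = np.full(len(timeline), NO_EVENT[stream], dtype=object)
    sub = episodes[
        (episodes["stream"] == stream) & (episodes["participant"] == participant)
    ]
    for _, row in sub.iterrows():
        lo = np.searchsorted(timeline, row.onset_s - 1e-9, side="left")
        hi = np.searchsorted(timeline, row.offset_s - 1e-9, side="left")
        labels[lo:hi] = row.label
    return labels


@dataclass
class FusedTrial:
    """Aligned 60 Hz categorical series for both participants of one trial."""

    dyad_id: str
    trial_index: int
    model_visibility: str
    talking: str
    duration_s: float
    time_s: np.ndarray
    aoi: dict[str, np.ndarray]
    action: dict[str, np.ndarray]
    gesture: dict[str, np.ndarray]
    speech: dict[str, np.ndarray]
    gaze_offset_s: dict[str, np.ndarray]
    episodes: pd.DataFrame = field(repr=False, default=None)

    @property
    def participants(self) -> tuple[str, str]:
        return tuple(sorted(self.aoi))

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    def partner_of(self, participant: str) -> str:
        a, b = self.participants
        if participant == a:
            return b
        if participant == b:
            return a
        raise KeyError(participant)

    def series(self, stream: str, participant: str) -> np.ndarray:
        return {"action": self.action, "gesture": self.gesture, "speech": self.speech}[
            stream
        ][participant]

    def to_frame(self) -> pd.DataFrame:
        """Long-format fused table (one row per participant-sample)."""
        frames = []
        for p in self.participants:
            frames.append(
                pd.DataFrame(
                    {
                        "dyad_id": self.dyad_id,
                        "trial_index": self.trial_index,
                        "participant": p,
                        "time_s": self.time_s,
                        "aoi": self.aoi[p],
                        "action": self.action[p],
                        "gesture": self.gesture[p],
                        "speech": self.speech[p],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def fuse_trial(trial: Trial) -> FusedTrial:
    """Fuse one trial into the aligned 60 Hz structure.

    The fused period is the intersection of gaze coverage (both
    participants, extended by one raw period at each edge) and the annotated
    ``[0, duration)``; shorter gaze coverage truncates the timeline with a
    warning. Fusion never imputes labels.
    """
    timeline = build_timeline(trial.duration_s)
    lo, hi = 0.0, trial.duration_s
    for gs in trial.gaze.values():
        period = 1.0 / gs.rate_hz
        lo = max(lo, gs.time_s[0] - period)
        hi = min(hi, gs.time_s[-1] + period)
    keep = (timeline >= lo - 1e-9) & (timeline <= hi + 1e-9)
    if not keep.all():
        warnings.warn(
            f"trial {trial.dyad_id}/{trial.trial_index}: gaze coverage "
            f"truncates fused timeline to [{lo:.3f}, {hi:.3f}] s",
            stacklevel=2,
        )
        timeline = timeline[keep]

    aoi, action, gesture, speech, offsets = {}, {}, {}, {}, {}
    for p in trial.participants:
        aoi[p], offsets[p] = assign_nearest_gaze(trial.gaze[p], timeline)
        action[p] = assign_episode_labels(trial.episodes, "action", p, timeline)
        gesture[p] = assign_episode_labels(trial.episodes, "gesture", p, timeline)
        speech[p] = assign_episode_labels(trial.episodes, "speech", p, timeline)
    return FusedTrial(
        dyad_id=trial.dyad_id,
        trial_index=trial.trial_index,
        model_visibility=trial.model_visibility,
        talking=trial.talking,
        duration_s=trial.duration_s,
        time_s=timeline,
        aoi=aoi,
        action=action,
        gesture=gesture,
        speech=speech,
        gaze_offset_s=offsets,
        episodes=trial.episodes,
    )


def fuse_session(session) -> list[FusedTrial]:
    """Fuse all four trials of a session."""
    return [fuse_trial(t) for t in session.trials]
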