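"""Synthetic dyadic sessions with known event processes and gaze coupling.

The generator emulates the study conditions: 19 dyads, four 60-s trials per
dyad crossing model visibility with whether talking is allowed, five-way
categorical gaze at 30 Hz, renewal-process manual actions (grab/place cycles
plus sparse remove/drop), sparse gestures, and on/off speech on talking
trials only.

Gaze is emitted from a softmax model: at each 30 Hz sample the log-odds of
the five AOIs are the log baseline marginals plus Gaussian *coupling
kernels* centred on event onsets,

    logit_a(t) = log pi_a + sum_k A_k exp(-(t - o_k - c_k)^2 / (2 w_k^2)),

summed over the onsets ``o_k`` of the kernel's event type from the
configured source (own or other participant). Samples are drawn i.i.d.
given the event context, which makes closed-form checks exact; an optional
sticky (first-order Markov) variant with a configurable stay probability is
available for robustness checks. Because the generating probabilities are
known, every downstream stage (timelock curves, dwell statistics, the
inference models) can be validated against ground truth.

Default rates and marginals follow the study's descriptive table: grab
9.25/min, place 8.50/min, remove 1.00/min, drop 1.12/min, point 1.62/min,
ask 0.25/min, instruct 0.25/min; speech occupies about 0.24 of talking-trial
time in about 12 utterances per minute; baseline AOI marginals blocks 0.11,
build 0.25, model 0.47, face 0.005, none 0.165.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    AOI_LABELS,
    EPISODE_COLUMNS,
    EVENT_LABELS,
    GazeStream,
    Session,
    Trial,
)
from .errors import ConfigurationError

RAW_RATE_HZ = 30.0

#: (visibility, talking) combinations; order is shuffled per dyad.
TRIAL_CONDITIONS = (
    ("visible", "forbidden"),
    ("visible", "allowed"),
    ("hidden", "forbidden"),
    ("hidden", "allowed"),
)

_STREAM_OF = {l: s for s, labels in EVENT_LABELS.items() for l in labels}


@dataclass(frozen=True)
class CouplingKernel:
    """A Gaussian log-odds bump tying one AOI to onsets of one event type.

    ``amplitude`` is in log-odds units, ``center_s`` the kernel centre
    relative to the event onset (negative = anticipatory gaze) and
    ``width_s`` the Gaussian standard deviation. ``source`` selects whose
    events drive the observer's gaze: their ``own`` or the ``other``
    participant's.
    """

    event_type: str
    source: str  # own | other
    aoi: str
    amplitude: float
    center_s: float = 0.0
    width_s: float = 0.4

    def __post_init__(self):
        if self.width_s <= 0:
            raise ConfigurationError("kernel width_s must be > 0")
        if self.source not in ("own", "other"):
            raise ConfigurationError(f"kernel source {self.source!r}")
        if self.aoi not in AOI_LABELS:
            raise ConfigurationError(f"kernel AOI {self.aoi!r}")
        if self.event_type not in _STREAM_OF:
            raise ConfigurationError(
                f"kernel references unknown event type {self.event_type!r}"
            )


def default_kernels() -> tuple[CouplingKernel, ...]:
    """Qualitative default coupling: strong own-action, weaker gestures and
    weak cross-person kernels (the study's ordering of effect sizes)."""
    return (
        CouplingKernel("grab", "own", "blocks", 2.0, 0.0, 0.5),
        CouplingKernel("place", "own", "build", 2.0, 0.0, 0.5),
        CouplingKernel("point", "own", "model", 1.0, 0.0, 0.7),
        CouplingKernel("ask", "own", "face", 3.0, 0.5, 1.0),
        CouplingKernel("instruct", "own", "face", 1.5, 0.5, 1.0),
        # cross-person coupling is present but weak
        CouplingKernel("grab", "other", "blocks", 0.75, 0.3, 0.6),
        CouplingKernel("place", "other", "build", 0.75, 0.3, 0.6),
        CouplingKernel("ask", "other", "face", 1.0, 0.5, 1.0),
    )


@dataclass
class GeneratorConfig:
    """All tunables of the synthetic study; defaults are the study conditions."""

    n_dyads: int = 19
    duration_s: float = 60.0
    baseline_aoi_probs: dict[str, float] = field(
        default_factory=lambda: {
            "blocks": 0.11,
            "build": 0.25,
            "model": 0.47,
            "face": 0.005,
            "none": 0.165,
        }
    )
    action_rates: dict[str, float] = field(
        default_factory=lambda: {"grab": 9.25, "place": 8.50, "remove": 1.00, "drop": 1.12}
    )
    gesture_rates: dict[str, float] = field(
        default_factory=lambda: {"point": 1.62, "ask": 0.25, "instruct": 0.25}
    )
    # log-normal episode durations: median (s) per type, common log-sd
    duration_medians_s: dict[str, float] = field(
        default_factory=lambda: {
            "grab": 1.4,
            "place": 2.3,
            "remove": 0.60,
            "drop": 0.55,
            "point": 1.48,
            "ask": 1.0,
            "instruct": 1.0,
        }
    )
    duration_log_sd: float = 0.4
    handling_gap_mean_s: float = 0.9  # grab -> place transport time
    speech_utterance_mean_s: float = 1.2  # 0 disables speech entirely
    speech_gap_mean_s: float = 3.8
    kernels: tuple[CouplingKernel, ...] = field(default_factory=default_kernels)
    stickiness: float = 0.0  # P(repeat previous AOI) before a fresh softmax draw
    seed: int = 0

    def validate(self) -> None:
        probs = np.array([self.baseline_aoi_probs[a] for a in AOI_LABELS])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("baseline_aoi_probs must sum to 1")
        if (probs < 0).any():
            raise ConfigurationError("baseline_aoi_probs must be non-negative")
        if self.n_dyads < 1:
            raise ConfigurationError("n_dyads must be >= 1")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        for rates in (self.action_rates, self.gesture_rates):
            if any(r < 0 for r in rates.values()):
                raise ConfigurationError("rates must be >= 0")
        if not 0 <= self.stickiness < 1:
            raise ConfigurationError("stickiness must be in [0, 1)")
        for k in self.kernels:
            if k.event_type not in _STREAM_OF:
                raise ConfigurationError(
                    f"kernel references unknown event type {k.event_type!r}"
                )
        # grab/place chain feasibility: mean cycle must exceed occupied time
        if self.action_rates.get("grab", 0) > 0:
            self._chain_gap_mean()

    # -- chain calibration --------------------------------------------------

    def _mean_duration(self, label: str) -> float:
        med = self.duration_medians_s[label]
        return med * float(np.exp(self.duration_log_sd**2 / 2))

    def _chain_gap_mean(self) -> float:
        """Mean idle gap before each grab so the grab rate is matched.

        The grab/place chain is a renewal process with mean cycle length
        60/grab_rate; each grab is followed by a place with probability
        place_rate/grab_rate (capped at 1).
        """
        grab_rate = self.action_rates["grab"]
        mu = 60.0 / grab_rate
        p_place = min(1.0, self.action_rates.get("place", 0.0) / grab_rate)
        gap = mu - self._mean_duration("grab") - p_place * (
            self.handling_gap_mean_s + self._mean_duration("place")
        )
        if gap <= 0.05:
            raise ConfigurationError(
                "action rates imply mean episode spacing shorter than mean "
                f"episode duration (residual gap {gap:.3f} s)"
            )
        return gap

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernels"] = [dataclasses.asdict(k) for k in self.kernels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["kernels"] = tuple(CouplingKernel(**k) for k in d.get("kernels", ()))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as f:
            return cls.from_dict(yaml.safe_load(f))


def default_config(**overrides) -> GeneratorConfig:
    """The study-calibrated default configuration (optionally overridden)."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Event-track generation
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, median: float, log_sd: float) -> float:
    return float(rng.lognormal(mean=np.log(median), sigma=log_sd))


def _overlaps(onset: float, offset: float, accepted: list[tuple[float, float]]) -> bool:
    return any(onset < b and a < offset for a, b in accepted)


def generate_event_tracks(
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant: str,
    talking: str,
) -> pd.DataFrame:
    """Episode table for one participant in one trial.

    Actions are an alternating grab→place renewal chain (burnt in so the
    grab rate is matched in expectation over the annotated minute) plus
    independent sparse remove/drop point processes thinned against the
    chain; gestures are independent sparse point processes thinned within
    the stream; speech is an alternating talking/quiet renewal process on
    talking trials only. Episodes are clipped to ``[0, duration)`` and never
    overlap within one (participant, stream).
    """
    config.validate()
    dur = config.duration_s
    rows: list[tuple] = []

    # grab/place chain
    grab_rate = config.action_rates.get("grab", 0.0)
    chain: list[tuple[float, float]] = []
    if grab_rate > 0:
        gap_mean = config._chain_gap_mean()
        p_place = min(1.0, config.action_rates.get("place", 0.0) / grab_rate)
        mu = 60.0 / grab_rate
        t = -max(30.0, 5.0 * mu)  # burn-in toward stationarity
        while t < dur:
            t += rng.exponential(gap_mean)
            onset = t
            t += _lognormal(rng, config.duration_medians_s["grab"], config.duration_log_sd)
            if 0.0 <= onset < dur:
                rows.append((participant, "action", "grab", onset, min(t, dur)))
                chain.append((onset, min(t, dur)))
            if rng.random() < p_place:
                t += rng.exponential(config.handling_gap_mean_s)
                onset = t
                t += _lognormal(
                    rng, config.duration_medians_s["place"], config.duration_log_sd
                )
                if 0.0 <= onset < dur:
                    rows.append((participant, "action", "place", onset, min(t, dur)))
                    chain.append((onset, min(t, dur)))

    # sparse independent processes, thinned to forbid within-stream overlap
    def sparse(stream: str, label: str, rate: float, accepted: list):
        if rate <= 0:
            return
        n = rng.poisson(rate * dur / 60.0)
        onsets = np.sort(rng.uniform(0.0, dur, size=n))
        for onset in onsets:
            offset = min(
                onset
                + _lognormal(rng, config.duration_medians_s[label], config.duration_log_sd),
                dur,
            )
            if offset > onset and not _overlaps(onset, offset, accepted):
                rows.append((participant, stream, label, float(onset), float(offset)))
                accepted.append((float(onset), float(offset)))

    action_busy = list(chain)
    for label in ("remove", "drop"):
        sparse("action", label, config.action_rates.get(label, 0.0), action_busy)
    gesture_busy: list[tuple[float, float]] = []
    for label in EVENT_LABELS["gesture"]:
        sparse("gesture", label, config.gesture_rates.get(label, 0.0), gesture_busy)

    # speech: alternating quiet/talking renewal on talking trials
    if talking == "allowed" and config.speech_utterance_mean_s > 0:
        sigma = config.duration_log_sd
        utter_median = config.speech_utterance_mean_s / float(np.exp(sigma**2 / 2))
        t = 0.0
        while t < dur:
            t += rng.exponential(config.speech_gap_mean_s)
            onset = t
            t += _lognormal(rng, utter_median, sigma)
            if 0.0 <= onset < dur:
                rows.append((participant, "speech", "talking", onset, min(t, dur)))

    df = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    return df.sort_values(["stream", "onset_s"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gaze generation
# ---------------------------------------------------------------------------

def gaze_probabilities(
    episodes: pd.DataFrame,
    config: GeneratorConfig,
    participant: str,
    partner: str,
    times: np.ndarray,
) -> np.ndarray:
    """Exact generating AOI probabilities (n_samples x 5) at the given times.

    This is the ground-truth softmax curve the observer's gaze is drawn
    from; it is exposed so downstream estimators can be validated against
    the generating model.
    """
    baseline = np.array([config.baseline_aoi_probs[a] for a in AOI_LABELS])
    logits = np.tile(np.log(np.clip(baseline, 1e-300, None)), (len(times), 1))
    aoi_index = {a: i for i, a in enumerate(AOI_LABELS)}
    for k in config.kernels:
        actor = participant if k.source == "own" else partner
        stream = _STREAM_OF[k.event_type]
        sub = episodes[
            (episodes["participant"] == actor)
            & (episodes["stream"] == stream)
            & (episodes["label"] == k.event_type)
        ]
        if sub.empty:
            continue
        onsets = sub["onset_s"].to_numpy(dtype=float)
        d = times[None, :] - onsets[:, None] - k.center_s
        bump = k.amplitude * np.exp(-(d**2) / (2.0 * k.width_s**2))
        logits[:, aoi_index[k.aoi]] += bump.sum(axis=0)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p


def generate_gaze(
    episodes: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant: str,
    partner: str,
) -> GazeStream:
    """Draw a 30 Hz categorical gaze stream from the softmax coupling model."""
    n = int(round(config.duration_s * RAW_RATE_HZ))
    times = np.arange(n) / RAW_RATE_HZ
    probs = gaze_probabilities(episodes, config, participant, partner, times)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    codes = (u[:, None] > cum).sum(axis=1)
    if config.stickiness > 0:
        stay = rng.random(n) < config.stickiness
        for i in range(1, n):
            if stay[i]:
                codes[i] = codes[i - 1]
    labels = np.array(AOI_LABELS, dtype=object)[codes]
    return GazeStream(
        participant=participant, rate_hz=RAW_RATE_HZ, time_s=times, aoi=labels
    )


# ---------------------------------------------------------------------------
# Sessions and datasets
# ---------------------------------------------------------------------------

def generate_session(
    config: GeneratorConfig, dyad_id: str, rng: np.random.Generator
) -> Session:
    """One dyad: four trials covering the 2x2 design in shuffled order."""
    p1, p2 = f"{dyad_id}_p1", f"{dyad_id}_p2"
    order = rng.permutation(len(TRIAL_CONDITIONS))
    trials = []
    for ti, ci in enumerate(order, start=1):
        visibility, talking = TRIAL_CONDITIONS[ci]
        parts = [
            generate_event_tracks(config, rng, p1, talking),
            generate_event_tracks(config, rng, p2, talking),
        ]
        parts = [df for df in parts if not df.empty]
        ep = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=EPISODE_COLUMNS)
        )
        gaze = {
            p1: generate_gaze(ep, config, rng, p1, p2),
            p2: generate_gaze(ep, config, rng, p2, p1),
        }
        trials.append(
            Trial(
                dyad_id=dyad_id,
                trial_index=ti,
                model_visibility=visibility,
                talking=talking,
                duration_s=config.duration_s,
                gaze=gaze,
                episodes=ep,
            )
        )
    session = Session(dyad_id=dyad_id, trials=trials)
    session.validate()
    return session


def generate_dataset(config: GeneratorConfig) -> list[Session]:
    """``n_dyads`` sessions, reproducible from ``config.seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_dyads)
    sessions = []
    for i, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        sessions.append(generate_session(config, f"d{i:02d}", rng))
    return sessions
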