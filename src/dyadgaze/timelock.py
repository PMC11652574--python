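"""Onset-locked proportion-of-looks curves.

For every instance of an event type (e.g., each grab action), the
observer's gaze AOI is read out at offsets τ ∈ [−3, +3] s on the 1/60-s
fused grid relative to the event onset. The onset is the first fused sample
during which the episode occurs. Curves are the mean over all pooled
instances of the indicator that gaze is on a given AOI at onset + τ —
pooled across all dyads and both participants, not a per-participant mean
of means. Instances whose window exceeds the trial bounds contribute only
their in-bounds offsets, so the instance count varies across τ.

Confidence intervals default to the normal approximation
p ± z·sqrt(p(1−p)/n) clipped to [0, 1]; Wilson intervals are available via
``ci_method="wilson"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AOI_LABELS, EVENT_LABELS, aoi_codes
from .errors import EmptyInputError
from .fusion import FUSED_RATE_HZ, FusedTrial

#: Window half-width in grid steps: 3 s at 60 Hz.
HALF_STEPS = 180
TAU_GRID = np.arange(-HALF_STEPS, HALF_STEPS + 1) / FUSED_RATE_HZ


class OnsetRecord(NamedTuple):
    trial: FusedTrial
    actor: str
    observer: str
    onset_idx: int
    onset_s: float


@dataclass
class OnsetSet:
    """All pooled onsets of one event type, with their observing participant."""

    stream: str
    event_type: str
    source: str  # own | other
    records: list[OnsetRecord]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.trial.dyad_id, r.trial.trial_index, r.actor, r.observer, r.onset_s)
                for r in self.records
            ],
            columns=["dyad_id", "trial_index", "actor", "observer", "onset_s"],
        )


def onset_sample_index(trial: FusedTrial, onset_s: float, offset_s: float) -> int | None:
    """Index of the first fused sample inside ``[onset, offset)``, or None."""
    idx = int(np.searchsorted(trial.time_s, onset_s - 1e-9, side="left"))
    if idx >= trial.n_samples or trial.time_s[idx] >= offset_s - 1e-9:
        return None
    return idx


def extract_onsets(
    fused: Iterable[FusedTrial], stream: str, event_type: str, source: str = "own"
) -> OnsetSet:
    """One onset per episode of ``event_type``; onset = first fused sample.

    For ``source="other"`` the observing participant is the partner of the
    acting participant. Episodes containing no fused sample (fully between
    grid points or outside coverage) are skipped.
    """
    if stream not in EVENT_LABELS or event_type not in EVENT_LABELS[stream]:
        raise ValueError(f"unknown event type {event_type!r} for stream {stream!r}")
    if source not in ("own", "other"):
        raise ValueError(f"source must be 'own' or 'other', got {source!r}")
    records: list[OnsetRecord] = []
    for trial in fused:
        ep = trial.episodes
        sub = ep[(ep["stream"] == stream) & (ep["label"] == event_type)]
        for _, row in sub.iterrows():
            idx = onset_sample_index(trial, row.onset_s, row.offset_s)
            if idx is None:
                continue
            actor = row.participant
            observer = actor if source == "own" else trial.partner_of(actor)
            records.append(OnsetRecord(trial, actor, observer, idx, float(row.onset_s)))
    return OnsetSet(stream=stream, event_type=event_type, source=source, records=records)


def onset_locked_counts(
    onsets: OnsetSet, half_steps: int = HALF_STEPS
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled AOI counts per offset: returns (counts[2h+1, 5], n[2h+1]).

    ``counts[k, a]`` is the number of instances whose observer fixated AOI
    ``a`` at grid offset ``k - half_steps``; ``n[k]`` the number of
    instances with that offset in-bounds.
    """
    counts = np.zeros((2 * half_steps + 1, len(AOI_LABELS)), dtype=np.int64)
    n = np.zeros(2 * half_steps + 1, dtype=np.int64)
    window = np.arange(-half_steps, half_steps + 1)
    # group records per (trial, observer) so gaze codes are computed once
    by_key: dict[tuple[int, str], tuple[FusedTrial, str, list[int]]] = {}
    for r in onsets.records:
        key = (id(r.trial), r.observer)
        by_key.setdefault(key, (r.trial, r.observer, []))[2].append(r.onset_idx)
    for trial, observer, idxs in by_key.values():
        codes = aoi_codes(trial.aoi[observer])
        pos = np.asarray(idxs)[:, None] + window[None, :]
        valid = (pos >= 0) & (pos < trial.n_samples)
        tau_i, flat = np.nonzero(valid)[1], pos[valid]
        sampled = codes[flat]
        np.add.at(counts, (tau_i, sampled), 1)
        np.add.at(n, tau_i, 1)
    return counts, n


@dataclass
class TimelockCurves:
    """Mean proportion of looks per AOI vs offset τ, with CI bands."""

    event_type: str
    source: str
    tau_s: np.ndarray
    mean: np.ndarray  # (361, 5)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray  # (361,)
    aoi_labels: tuple[str, ...] = AOI_LABELS

    def curve(self, aoi: str) -> np.ndarray:
        return self.mean[:, self.aoi_labels.index(aoi)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, a in enumerate(self.aoi_labels):
            rows.append(
                pd.DataFrame(
                    {
                        "event_type": self.event_type,
                        "source": self.source,
                        "tau_s": self.tau_s,
                        "aoi": a,
                        "mean": self.mean[:, j],
                        "ci_lo": self.ci_lo[:, j],
                        "ci_hi": self.ci_hi[:, j],
                        "n": self.n,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def timelock_proportions(
    onsets: OnsetSet, ci_method: str = "normal", alpha: float = 0.05
) -> TimelockCurves:
    """Onset-locked mean proportions with per-τ confidence intervals."""
    if len(onsets) == 0:
        raise EmptyInputError(
            f"no onsets of {onsets.event_type!r}; cannot compute curves"
        )
    counts, n = onset_locked_counts(onsets)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n[:, None] > 0, counts / np.maximum(n[:, None], 1), np.nan)
    if ci_method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        se = np.sqrt(mean * (1 - mean) / np.maximum(n[:, None], 1))
        lo = np.clip(mean - z * se, 0.0, 1.0)
        hi = np.clip(mean + z * se, 0.0, 1.0)
    elif ci_method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(
            counts, np.maximum(n[:, None], 1), alpha=alpha, method="wilson"
        )
        lo, hi = np.asarray(lo), np.asarray(hi)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return TimelockCurves(
        event_type=onsets.event_type,
        source=onsets.source,
        tau_s=TAU_GRID.copy(),
        mean=mean,
        ci_lo=lo,
        ci_hi=hi,
        n=n,
    )


@dataclass
class PeakSummary:
    """Start / max / min of one AOI's curve with their τ locations and CIs."""

    aoi: str
    start: float
    start_ci: tuple[float, float]
    max: float
    max_tau_s: float
    max_ci: tuple[float, float]
    min: float
    min_tau_s: float
    min_ci: tuple[float, float]


def peak_summary(curves: TimelockCurves, aoi: str) -> PeakSummary:
    """Curve value at τ = −3 s plus the extrema over the window with CIs."""
    if aoi not in curves.aoi_labels:
        raise ValueError(f"unknown AOI {aoi!r}")
    j = curves.aoi_labels.index(aoi)
    y = curves.mean[:, j]
    finite = np.isfinite(y)
    if not finite.any():
        raise EmptyInputError("curve has no populated offsets")
    i_start = int(np.flatnonzero(finite)[0])
    masked = np.where(finite, y, -np.inf)
    i_max = int(np.argmax(masked))
    masked = np.where(finite, y, np.inf)
    i_min = int(np.argmin(masked))
    return PeakSummary(
        aoi=aoi,
        start=float(y[i_start]),
        start_ci=(float(curves.ci_lo[i_start, j]), float(curves.ci_hi[i_start, j])),
        max=float(y[i_max]),
        max_tau_s=float(curves.tau_s[i_max]),
        max_ci=(float(curves.ci_lo[i_max, j]), float(curves.ci_hi[i_max, j])),
        min=float(y[i_min]),
        min_tau_s=float(curves.tau_s[i_min]),
        min_ci=(float(curves.ci_lo[i_min, j]), float(curves.ci_hi[i_min, j])),
    )
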