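"""Episode-conditional relative dwell time on an AOI.

The relative total dwell time on a target AOI during a behavior category is
the fraction of fused samples in that category state during which gaze was
on the target AOI. It is computed per trial; a per-participant value is the
unweighted mean over trials with at least one sample in the category
(missing, not zero, otherwise). Speech-conditioned dwell uses only trials
where talking was allowed. With ``source="other"`` the category state is
read from the partner's stream while gaze remains the participant's own —
this quantifies gaze attracted by the partner's behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import EVENT_LABELS, NO_EVENT
from .fusion import FusedTrial


def _valid_category(stream: str, category: str) -> None:
    if stream not in EVENT_LABELS:
        raise ValueError(f"unknown stream {stream!r}")
    if category not in EVENT_LABELS[stream] + (NO_EVENT[stream],):
        raise ValueError(f"unknown category {category!r} for stream {stream!r}")


def dwell_during(
    fused: FusedTrial,
    participant: str,
    target_aoi: str,
    stream: str,
    category: str,
    source: str = "own",
) -> float:
    """Relative dwell on ``target_aoi`` while ``stream`` is in ``category``.

    Returns NaN (missing) when the trial contains no sample in the category
    — including speech categories in no-talk trials, where speech was never
    annotated.
    """
    _valid_category(stream, category)
    if source not in ("own", "other"):
        raise ValueError(f"source must be 'own' or 'other', got {source!r}")
    if stream == "speech" and fused.talking != "allowed":
        return math.nan
    actor = participant if source == "own" else fused.partner_of(participant)
    state = fused.series(stream, actor)
    mask = state == category
    denom = int(mask.sum())
    if denom == 0:
        return math.nan
    return float(np.mean(fused.aoi[participant][mask] == target_aoi))


@dataclass
class DwellResult:
    """Per-trial and per-participant relative dwell for one condition."""

    participant: str
    target_aoi: str
    stream: str
    category: str
    source: str
    per_trial: list[float]  # NaN where missing
    mean: float  # NaN if all trials missing
    n_trials_used: int


def per_participant_dwell(
    fused_trials: Iterable[FusedTrial],
    participant: str,
    target_aoi: str,
    stream: str,
    category: str,
    source: str = "own",
    weight_by_duration: bool = False,
) -> DwellResult:
    """Unweighted mean of non-missing per-trial dwell fractions.

    ``weight_by_duration=True`` instead weights each trial's fraction by the
    number of samples in the category (a sensitivity variant).
    """
    fracs, weights = [], []
    for ft in fused_trials:
        f = dwell_during(ft, participant, target_aoi, stream, category, source)
        fracs.append(f)
        if weight_by_duration and not math.isnan(f):
            actor = participant if source == "own" else ft.partner_of(participant)
            weights.append(int(np.sum(ft.series(stream, actor) == category)))
        elif not math.isnan(f):
            weights.append(1)
    avail = [f for f in fracs if not math.isnan(f)]
    if avail:
        mean = float(np.average(avail, weights=weights))
    else:
        mean = math.nan
    return DwellResult(
        participant=participant,
        target_aoi=target_aoi,
        stream=stream,
        category=category,
        source=source,
        per_trial=fracs,
        mean=mean,
        n_trials_used=len(avail),
    )


def dwell_table(
    sessions_fused: Sequence[Sequence[FusedTrial]],
    target_aoi: str,
    stream: str,
    categories: Sequence[str] | None = None,
    source: str = "own",
) -> pd.DataFrame:
    """Per-participant dwell for each category across a fused dataset.

    Returns one row per (participant, category) with the per-participant
    mean and the number of contributing trials.
    """
    if categories is None:
        categories = EVENT_LABELS[stream] + (NO_EVENT[stream],)
    rows = []
    for fused_trials in sessions_fused:
        participants = fused_trials[0].participants
        for p in participants:
            for cat in categories:
                r = per_participant_dwell(
                    fused_trials, p, target_aoi, stream, cat, source
                )
                rows.append(
                    {
                        "participant": p,
                        "source": source,
                        "stream": stream,
                        "category": cat,
                        "target_aoi": target_aoi,
                        "mean": r.mean,
                        "n_trials_used": r.n_trials_used,
                    }
                )
    return pd.DataFrame(rows)


def group_dwell_summary(dwell: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SE across non-missing participants per category, with counts."""
    rows = []
    for cat, grp in dwell.groupby("category", sort=False):
        vals = grp["mean"].dropna().to_numpy()
        rows.append(
            {
                "category": cat,
                "group_mean": float(np.mean(vals)) if len(vals) else math.nan,
                "group_se": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else math.nan,
                "n_participants": len(vals),
            }
        )
    return pd.DataFrame(rows)
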