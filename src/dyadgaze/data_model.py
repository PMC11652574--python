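"""Domain types and tidy CSV I/O for dyadic multimodal session data.

A *session* is one dyad's annotated recording: four 60-s trials crossing
model visibility (visible/hidden) with whether talking was allowed. Each
trial carries one categorical gaze stream per participant (each sample
assigned to one of five areas of interest) and an episode table of manual
actions (grab, place, remove, drop), gestures (point, ask, instruct) and
speech utterances (talking), each with an onset and offset in seconds.

Conventions
-----------
* Time origin: the annotated segment of every trial starts at t = 0 s;
  onsets/offsets are trial-relative seconds.
* Episode intervals are half-open ``[onset, offset)``: a sample exactly at
  the offset instant lies outside the episode, so abutting episodes never
  share a sample.
* Speech in no-talk trials is represented by an *empty* episode set (the
  all-"quiet" samples arise at fusion time), mirroring the way episode
  membership is resolved downstream.
* The two participants of a dyad are unordered; "the other person" is
  resolved per analysis call via :meth:`Trial.partner_of`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError

#: The five admissible gaze areas of interest. Every gaze sample carries
#: exactly one of these.
AOI_LABELS: tuple[str, ...] = ("blocks", "build", "model", "face", "none")

#: Deterministic tie-break priority used wherever a modal/argmax AOI must be
#: unique (ordering follows overall fixation frequency in this task).
AOI_PRIORITY: tuple[str, ...] = ("model", "build", "blocks", "face", "none")

STREAMS: tuple[str, ...] = ("action", "gesture", "speech")

#: Episode labels per stream (excluding the no-episode state).
EVENT_LABELS: dict[str, tuple[str, ...]] = {
    "action": ("grab", "place", "remove", "drop"),
    "gesture": ("point", "ask", "instruct"),
    "speech": ("talking",),
}

#: The no-episode state per stream, assigned at fusion time.
NO_EVENT: dict[str, str] = {"action": "none", "gesture": "none", "speech": "quiet"}

EPISODE_COLUMNS = ["participant", "stream", "label", "onset_s", "offset_s"]

_AOI_CODE = {a: i for i, a in enumerate(AOI_LABELS)}


def aoi_codes(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """Map AOI label strings to compact integer codes (order of AOI_LABELS)."""
    arr = np.asarray(labels)
    try:
        return np.fromiter((_AOI_CODE[x] for x in arr), dtype=np.int8, count=len(arr))
    except KeyError as exc:  # pragma: no cover - guarded by validation
        raise SchemaError(f"unknown AOI label {exc.args[0]!r}") from exc


@dataclass
class GazeStream:
    """A categorical gaze time series for one participant in one trial."""

    participant: str
    rate_hz: float
    time_s: np.ndarray
    aoi: np.ndarray

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.aoi = np.asarray(self.aoi, dtype=object)

    def validate(self, file: str | None = None) -> None:
        if len(self.time_s) != len(self.aoi):
            raise SchemaError("time and aoi lengths differ", file=file)
        if len(self.time_s) == 0:
            raise SchemaError("empty gaze stream", file=file)
        if not np.all(np.diff(self.time_s) > 0):
            bad = int(np.flatnonzero(np.diff(self.time_s) <= 0)[0]) + 1
            raise SchemaError("time strictly increasing", file=file, row=bad)
        unknown = set(self.aoi) - set(AOI_LABELS)
        if unknown:
            raise SchemaError(f"unknown AOI label(s) {sorted(unknown)}", file=file)
        if len(self.time_s) > 1:
            rate = 1.0 / float(np.median(np.diff(self.time_s)))
            if abs(rate - self.rate_hz) > 0.1 * self.rate_hz:
                raise SchemaError(
                    f"sampling rate {rate:.2f} Hz departs >10% from nominal "
                    f"{self.rate_hz:g} Hz",
                    file=file,
                )

    def __eq__(self, other):
        return (
            isinstance(other, GazeStream)
            and self.participant == other.participant
            and self.rate_hz == other.rate_hz
            and len(self.time_s) == len(other.time_s)
            and np.allclose(self.time_s, other.time_s, atol=1e-6)
            and np.array_equal(self.aoi, other.aoi)
        )


def validate_episodes(
    episodes: pd.DataFrame,
    duration_s: float,
    participants: Sequence[str],
    talking: str,
    file: str | None = None,
) -> pd.DataFrame:
    """Check an episode table against the trial invariants, returning it sorted.

    Raises :class:`SchemaError` on missing columns, unknown labels, inverted
    or out-of-range intervals, overlapping episodes within one
    (participant, stream), or speech episodes in a no-talk trial.
    """
    missing = [c for c in EPISODE_COLUMNS if c not in episodes.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}", file=file)
    ep = episodes.loc[:, EPISODE_COLUMNS].copy()
    ep["onset_s"] = ep["onset_s"].astype(float)
    ep["offset_s"] = ep["offset_s"].astype(float)
    for idx, row in ep.iterrows():
        if row.stream not in STREAMS:
            raise SchemaError(f"unknown stream {row.stream!r}", file=file, row=idx)
        if row.label not in EVENT_LABELS[row.stream]:
            raise SchemaError(
                f"unknown label {row.label!r} for stream {row.stream!r}",
                file=file,
                row=idx,
            )
        if row.participant not in participants:
            raise SchemaError(
                f"unknown participant {row.participant!r}", file=file, row=idx
            )
        if not row.onset_s < row.offset_s:
            raise SchemaError("onset < offset", file=file, row=idx)
        if row.onset_s < 0 or row.offset_s > duration_s + 1e-9:
            raise SchemaError("episode within [0, trial duration]", file=file, row=idx)
    if talking == "forbidden" and (ep["stream"] == "speech").any():
        raise SchemaError("speech episodes in a no-talk trial", file=file)
    ep = ep.sort_values(["participant", "stream", "onset_s"], kind="stable")
    for (p, s), grp in ep.groupby(["participant", "stream"], sort=False):
        if (grp["onset_s"].to_numpy()[1:] < grp["offset_s"].to_numpy()[:-1] - 1e-12).any():
            raise SchemaError(
                f"overlapping episodes for participant={p} stream={s}", file=file
            )
    return ep.reset_index(drop=True)


@dataclass
class Trial:
    """One annotated 60-s trial of a dyad."""

    dyad_id: str
    trial_index: int
    model_visibility: str  # visible | hidden
    talking: str  # allowed | forbidden
    duration_s: float
    gaze: dict[str, GazeStream]
    episodes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EPISODE_COLUMNS))

    @property
    def participants(self) -> tuple[str, str]:
        return tuple(sorted(self.gaze))

    def partner_of(self, participant: str) -> str:
        a, b = self.participants
        if participant == a:
            return b
        if participant == b:
            return a
        raise KeyError(participant)

    def validate(self, file: str | None = None) -> None:
        if self.model_visibility not in ("visible", "hidden"):
            raise SchemaError(
                f"model_visibility {self.model_visibility!r}", file=file
            )
        if self.talking not in ("allowed", "forbidden"):
            raise SchemaError(f"talking {self.talking!r}", file=file)
        if self.duration_s <= 0:
            raise SchemaError("duration_s must be positive", file=file)
        if len(self.gaze) != 2:
            raise SchemaError("exactly two participants per trial", file=file)
        for stream in self.gaze.values():
            stream.validate(file=file)
        self.episodes = validate_episodes(
            self.episodes, self.duration_s, self.participants, self.talking, file=file
        )


@dataclass
class Session:
    """Four trials of one dyad, covering the 2x2 condition design once each."""

    dyad_id: str
    trials: list[Trial]

    @property
    def participants(self) -> tuple[str, str]:
        return self.trials[0].participants

    def validate(self) -> None:
        if len(self.trials) != 4:
            raise SchemaError(f"session {self.dyad_id}: expected 4 trials")
        combos = {(t.model_visibility, t.talking) for t in self.trials}
        if len(combos) != 4:
            raise SchemaError(
                f"session {self.dyad_id}: trials must cover all four "
                "visibility x talking combinations exactly once"
            )
        for t in self.trials:
            t.validate()
            if t.participants != self.participants:
                raise SchemaError(
                    f"session {self.dyad_id}: participant ids differ across trials"
                )


# ---------------------------------------------------------------------------
# Tidy CSV I/O
#
# Layout of a session directory:
#   trials.csv   dyad_id, trial_index, model_visibility, talking, duration_s
#   gaze.csv     dyad_id, trial_index, participant, time_s, aoi
#   episodes.csv dyad_id, trial_index, participant, stream, label, onset_s, offset_s
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["dyad_id", "trial_index", "model_visibility", "talking", "duration_s"]
_GAZE_COLUMNS = ["dyad_id", "trial_index", "participant", "time_s", "aoi"]
_EP_FILE_COLUMNS = ["dyad_id", "trial_index"] + EPISODE_COLUMNS


def _require_columns(df: pd.DataFrame, cols: list[str], file: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}", file=file)


def read_session(path: str | Path) -> Session:
    """Read and validate one session directory written by :func:`write_session`."""
    path = Path(path)
    trials_f, gaze_f, ep_f = (path / n for n in ("trials.csv", "gaze.csv", "episodes.csv"))
    trials_df = pd.read_csv(trials_f)
    gaze_df = pd.read_csv(gaze_f, dtype={"participant": str})
    ep_df = pd.read_csv(ep_f, dtype={"participant": str})
    _require_columns(trials_df, _TRIAL_COLUMNS, str(trials_f))
    _require_columns(gaze_df, _GAZE_COLUMNS, str(gaze_f))
    _require_columns(ep_df, _EP_FILE_COLUMNS, str(ep_f))

    dyads = trials_df["dyad_id"].unique()
    if len(dyads) != 1:
        raise SchemaError("one dyad per session directory", file=str(trials_f))
    dyad_id = str(dyads[0])

    trials: list[Trial] = []
    for _, trow in trials_df.sort_values("trial_index").iterrows():
        ti = int(trow.trial_index)
        gsub = gaze_df[gaze_df["trial_index"] == ti]
        streams: dict[str, GazeStream] = {}
        for p, psub in gsub.groupby("participant", sort=True):
            t = psub["time_s"].to_numpy(dtype=float)
            if len(t) > 1:
                rate = round(1.0 / float(np.median(np.diff(t))))
            else:
                rate = 30.0
            streams[str(p)] = GazeStream(
                participant=str(p),
                rate_hz=float(rate),
                time_s=t,
                aoi=psub["aoi"].to_numpy(dtype=object),
            )
        esub = ep_df[ep_df["trial_index"] == ti].loc[:, EPISODE_COLUMNS]
        trial = Trial(
            dyad_id=dyad_id,
            trial_index=ti,
            model_visibility=str(trow.model_visibility),
            talking=str(trow.talking),
            duration_s=float(trow.duration_s),
            gaze=streams,
            episodes=esub.reset_index(drop=True),
        )
        trial.validate(file=str(path))
        trials.append(trial)
    session = Session(dyad_id=dyad_id, trials=trials)
    session.validate()
    return session


def write_session(session: Session, path: str | Path) -> list[Path]:
    """Write a session to three tidy CSVs; inverse of :func:`read_session`.

    Timestamps are written with microsecond precision, so read∘write is an
    identity up to 1e-6 s on times and exact on every categorical field.
    """
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    trows, grows, erows = [], [], []
    for t in session.trials:
        trows.append(
            [t.dyad_id, t.trial_index, t.model_visibility, t.talking, t.duration_s]
        )
        for p in t.participants:
            gs = t.gaze[p]
            grows.append(
                pd.DataFrame(
                    {
                        "dyad_id": t.dyad_id,
                        "trial_index": t.trial_index,
                        "participant": p,
                        "time_s": gs.time_s,
                        "aoi": gs.aoi,
                    }
                )
            )
        ep = t.episodes.copy()
        ep.insert(0, "trial_index", t.trial_index)
        ep.insert(0, "dyad_id", t.dyad_id)
        erows.append(ep)

    trials_df = pd.DataFrame(trows, columns=_TRIAL_COLUMNS)
    gaze_df = pd.concat(grows, ignore_index=True)
    ep_df = (
        pd.concat(erows, ignore_index=True)
        if erows
        else pd.DataFrame(columns=_EP_FILE_COLUMNS)
    )
    files = []
    for name, df in (
        ("trials.csv", trials_df),
        ("gaze.csv", gaze_df),
        ("episodes.csv", ep_df),
    ):
        f = path / name
        df.to_csv(f, index=False, float_format="%.6f")
        files.append(f)
    return files


def write_dataset(sessions: Iterable[Session], root: str | Path) -> list[Path]:
    """Write each session to ``root/<dyad_id>/`` (deterministic naming)."""
    root = Path(root)
    dirs = []
    for s in sessions:
        d = root / s.dyad_id
        write_session(s, d)
        dirs.append(d)
    return dirs


def read_dataset(root: str | Path) -> list[Session]:
    """Read every session directory under ``root`` (sorted by dyad id)."""
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if (p / "trials.csv").exists())
    if not dirs:
        raise EmptyInputError(f"no session directories under {root}")
    return [read_session(d) for d in dirs]


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def describe_dataset(sessions: Sequence[Session]) -> pd.DataFrame:
    """Medians and ranges across participants of per-participant behavior means.

    For every behavior category this reports the median and range across
    participants of the per-participant mean proportion of trial time and
    frequency (instances per minute). Gaze, action and gesture means are
    taken over the four trials; speech means over the two talking trials.
    Total occurrence counts are reported for actions and gestures.

    Returns a frame indexed by (stream, label) with columns
    ``prop_median, prop_min, prop_max, freq_median, freq_min, freq_max,
    occurrences``.
    """
    sessions = list(sessions)
    if not sessions or not any(s.trials for s in sessions):
        raise EmptyInputError("describe_dataset requires at least one session")

    # per participant: {(stream,label): [per-trial proportion], ...}
    prop: dict[str, dict[tuple, list]] = {}
    freq: dict[str, dict[tuple, list]] = {}
    occurrences: dict[tuple, int] = {}

    def acc(d, p, key, value):
        d.setdefault(p, {}).setdefault(key, []).append(value)

    for s in sessions:
        for t in s.trials:
            minutes = t.duration_s / 60.0
            for p in t.participants:
                gs = t.gaze[p]
                for a in AOI_LABELS:
                    acc(prop, p, ("gaze", a), float(np.mean(gs.aoi == a)))
                # per-AOI visit frequency: count maximal runs of each AOI
                lab = gs.aoi
                boundaries = np.flatnonzero(
                    np.r_[True, lab[1:] != lab[:-1]]
                )
                run_labels = lab[boundaries]
                for a in AOI_LABELS:
                    acc(freq, p, ("gaze", a), float(np.sum(run_labels == a) / minutes))
                ep = t.episodes
                for stream in ("action", "gesture"):
                    occupied = 0.0
                    for label in EVENT_LABELS[stream]:
                        sub = ep[
                            (ep["participant"] == p)
                            & (ep["stream"] == stream)
                            & (ep["label"] == label)
                        ]
                        dur = float((sub["offset_s"] - sub["onset_s"]).sum())
                        occupied += dur
                        acc(prop, p, (stream, label), dur / t.duration_s)
                        acc(freq, p, (stream, label), len(sub) / minutes)
                        occurrences[(stream, label)] = occurrences.get(
                            (stream, label), 0
                        ) + len(sub)
                    acc(prop, p, (stream, "none"), 1.0 - occupied / t.duration_s)
                if t.talking == "allowed":
                    sub = ep[(ep["participant"] == p) & (ep["stream"] == "speech")]
                    dur = float((sub["offset_s"] - sub["onset_s"]).sum())
                    acc(prop, p, ("speech", "talking"), dur / t.duration_s)
                    acc(prop, p, ("speech", "quiet"), 1.0 - dur / t.duration_s)
                    acc(freq, p, ("speech", "talking"), len(sub) / minutes)

    keys = (
        [("gaze", a) for a in AOI_LABELS]
        + [("action", l) for l in EVENT_LABELS["action"] + ("none",)]
        + [("gesture", l) for l in EVENT_LABELS["gesture"] + ("none",)]
        + [("speech", "talking"), ("speech", "quiet")]
    )
    rows = []
    for key in keys:
        pvals = [np.mean(v[key]) for v in prop.values() if key in v]
        fvals = [np.mean(v.get(key, [np.nan])) for v in freq.values() if key in v]
        rows.append(
            {
                "stream": key[0],
                "label": key[1],
                "prop_median": float(np.median(pvals)) if pvals else np.nan,
                "prop_min": float(np.min(pvals)) if pvals else np.nan,
                "prop_max": float(np.max(pvals)) if pvals else np.nan,
                "freq_median": float(np.nanmedian(fvals)) if fvals else np.nan,
                "freq_min": float(np.nanmin(fvals)) if fvals else np.nan,
                "freq_max": float(np.nanmax(fvals)) if fvals else np.nan,
                "occurrences": occurrences.get(key, np.nan),
            }
        )
    return pd.DataFrame(rows).set_index(["stream", "label"])
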