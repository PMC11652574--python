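"""Conditional-probability gaze inference with leave-one-pair-out evaluation.

Six models infer a participant's gaze AOI from event onsets: their own
actions, gestures or speech episodes, or the partner's. Training estimates,
per event type, the conditional probability of fixating each of the five
AOIs at offsets τ ∈ [−3, +3] s (1/60-s grid) around the onsets, pooled over
all training pairs. To infer the gaze label at a sample, the probability
vectors of all onsets within ±3 s are averaged at their respective offsets
and the argmax AOI assigned; samples with no onset in the window receive
the fallback AOI — the most frequently fixated AOI across the training
data. The benchmark model emits the fallback AOI everywhere, so its score
for a held-out pair equals that pair's proportion of gaze on the training
modal AOI.

Evaluation is leave-one-pair-out: train on all dyads but one, score the
held-out dyad's four trials (both participants pooled per trial), average
per pair over trials and then across pairs (unweighted).

The public surface is a statsmodels-style pair: :class:`GazeInferenceModel`
holds the data and specification; :meth:`GazeInferenceModel.fit` runs the
cross-validation and returns a :class:`GazeInferenceResults` carrying the
per-pair scores, their dispersion, the benchmark counterparts and a
``summary()`` table. :func:`loocv_evaluate` is the functional shorthand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AOI_LABELS, AOI_PRIORITY, EVENT_LABELS, Session, aoi_codes
from .errors import EmptyInputError
from .fusion import FusedTrial, fuse_session
from .timelock import extract_onsets, onset_locked_counts, onset_sample_index

#: column permutation so that np.argmax (first-max wins) realizes the fixed
#: AOI tie priority model > build > blocks > face > none
_PRIORITY_IDX = np.array([AOI_LABELS.index(a) for a in AOI_PRIORITY])


def _argmax_priority(vectors: np.ndarray) -> np.ndarray:
    """Row-wise argmax over AOI probabilities with deterministic tie-break."""
    picks = np.argmax(vectors[..., _PRIORITY_IDX], axis=-1)
    return _PRIORITY_IDX[picks]


@dataclass(frozen=True)
class ModelSpec:
    """Which event stream and whose events predict gaze."""

    stream: str  # action | gesture | speech
    source: str  # own | other
    half_width_s: float = 3.0
    step_s: float = 1.0 / 60.0

    def __post_init__(self):
        if self.stream not in EVENT_LABELS:
            raise ValueError(f"unknown stream {self.stream!r}")
        if self.source not in ("own", "other"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.half_width_s <= 0:
            raise ValueError("half_width_s must be > 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.half_width_s / self.step_s))

    @property
    def name(self) -> str:
        return f"{self.source}_{self.stream}"


ALL_SPECS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(stream=s, source=src)
    for src in ("own", "other")
    for s in ("action", "gesture", "speech")
)


@dataclass
class CondProbTable:
    """Trained conditional probabilities per event type over the τ grid."""

    spec: ModelSpec
    probs: dict[str, np.ndarray]  # event type -> (2*n_steps+1, 5), rows sum to 1
    counts: dict[str, np.ndarray]  # event type -> (2*n_steps+1,)
    marginal: np.ndarray  # (5,) training-wide AOI distribution
    fallback_aoi: str

    @property
    def fallback_code(self) -> int:
        return AOI_LABELS.index(self.fallback_aoi)


def _training_marginal(fused: Sequence[FusedTrial]) -> np.ndarray:
    counts = np.zeros(len(AOI_LABELS), dtype=np.int64)
    for ft in fused:
        for p in ft.participants:
            counts += np.bincount(aoi_codes(ft.aoi[p]), minlength=len(AOI_LABELS))
    if counts.sum() == 0:
        raise EmptyInputError("training set contains no gaze samples")
    return counts / counts.sum()


def benchmark_majority(fused: Sequence[FusedTrial]) -> str:
    """Modal gaze AOI across all training samples (deterministic tie rule)."""
    marginal = _training_marginal(list(fused))
    return AOI_LABELS[int(_argmax_priority(marginal[None, :])[0])]


def train_table(
    fused: Sequence[FusedTrial], spec: ModelSpec, pooled: bool = False
) -> CondProbTable:
    """Estimate the conditional-probability table from training trials.

    Curves are per event type within the stream (``pooled=True`` merges all
    types of the stream into one curve, a sensitivity variant). Offsets with
    zero training instances — and event types absent from training — fall
    back to the training marginal AOI distribution.
    """
    fused = list(fused)
    if not fused:
        raise EmptyInputError("empty training set")
    marginal = _training_marginal(fused)
    probs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    types = EVENT_LABELS[spec.stream]
    per_type = {
        t: onset_locked_counts(
            extract_onsets(fused, spec.stream, t, spec.source), spec.n_steps
        )
        for t in types
    }
    if pooled:
        c = sum(c for c, _ in per_type.values())
        n = sum(n for _, n in per_type.values())
        per_type = {t: (c, n) for t in types}
    for t, (c, n) in per_type.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            p = c / np.maximum(n[:, None], 1)
        p = np.where(n[:, None] > 0, p, marginal[None, :])
        probs[t] = p
        counts[t] = n
    return CondProbTable(
        spec=spec,
        probs=probs,
        counts=counts,
        marginal=marginal,
        fallback_aoi=AOI_LABELS[int(_argmax_priority(marginal[None, :])[0])],
    )


def _predictor_onsets(
    fused: FusedTrial, participant: str, spec: ModelSpec
) -> list[tuple[str, int]]:
    """(event type, onset sample index) pairs driving this participant's model."""
    actor = participant if spec.source == "own" else fused.partner_of(participant)
    ep = fused.episodes
    sub = ep[(ep["stream"] == spec.stream) & (ep["participant"] == actor)]
    out = []
    for _, row in sub.iterrows():
        idx = onset_sample_index(fused, row.onset_s, row.offset_s)
        if idx is not None:
            out.append((row.label, idx))
    return out


def infer_gaze(
    table: CondProbTable, fused: FusedTrial, participant: str, spec: ModelSpec | None = None
) -> np.ndarray:
    """Inferred AOI label series for one participant in one trial.

    For each fused sample, the type-specific probability vectors of all
    predictor onsets within the window (closed bounds, |t − onset| ≤ 3 s on
    the grid) are averaged at their offsets; the argmax AOI is assigned.
    Samples with no onset in the window get the fallback AOI.
    """
    spec = spec or table.spec
    n = fused.n_samples
    acc = np.zeros((n, len(AOI_LABELS)))
    cnt = np.zeros(n, dtype=np.int64)
    half = spec.n_steps
    for label, idx0 in _predictor_onsets(fused, participant, spec):
        lo = max(0, idx0 - half)
        hi = min(n, idx0 + half + 1)
        seg = table.probs[label][lo - idx0 + half : hi - idx0 + half]
        acc[lo:hi] += seg
        cnt[lo:hi] += 1
    pred = np.full(n, table.fallback_code, dtype=np.int64)
    covered = cnt > 0
    if covered.any():
        pred[covered] = _argmax_priority(acc[covered])
    return np.array(AOI_LABELS, dtype=object)[pred]


def score(inferred: np.ndarray, actual: np.ndarray) -> float:
    """Proportion of samples with matching AOI labels."""
    inferred = np.asarray(inferred)
    actual = np.asarray(actual)
    if inferred.shape != actual.shape:
        raise ValueError(
            f"length mismatch: inferred {inferred.shape} vs actual {actual.shape}"
        )
    return float(np.mean(inferred == actual))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class GazeInferenceModel:
    """A conditional-probability gaze-inference model over a dyadic dataset.

    Parameters
    ----------
    sessions
        The dataset, either :class:`~dyadgaze.data_model.Session` objects or
        pre-fused trial lists (one list per dyad).
    spec
        Which stream and source predict gaze.
    pooled
        Merge all event types of the stream into one curve (sensitivity
        variant); default keeps per-type curves.
    """

    def __init__(
        self,
        sessions: Sequence[Session] | Sequence[Sequence[FusedTrial]],
        spec: ModelSpec,
        pooled: bool = False,
    ):
        sessions = list(sessions)
        if len(sessions) < 2:
            raise EmptyInputError(
                "leave-one-pair-out evaluation requires at least 2 sessions"
            )
        self.spec = spec
        self.pooled = pooled
        self.fused: list[list[FusedTrial]] = [
            list(s) if not isinstance(s, Session) else fuse_session(s)
            for s in sessions
        ]
        self.dyad_ids = [ft[0].dyad_id for ft in self.fused]

    def train_full(self) -> CondProbTable:
        """Table trained on the complete dataset (no hold-out)."""
        return train_table(
            [ft for sess in self.fused for ft in sess], self.spec, self.pooled
        )

    def fit(self) -> "GazeInferenceResults":
        """Leave-one-pair-out cross-validation of model and benchmark."""
        rows = []
        for i, held_out in enumerate(self.fused):
            training = [ft for j, sess in enumerate(self.fused) if j != i for ft in sess]
            table = train_table(training, self.spec, self.pooled)
            for ft in held_out:
                inferred, actual = [], []
                for p in ft.participants:
                    inferred.append(infer_gaze(table, ft, p, self.spec))
                    actual.append(ft.aoi[p])
                inferred = np.concatenate(inferred)
                actual = np.concatenate(actual)
                bench = np.full(len(actual), table.fallback_aoi, dtype=object)
                rows.append(
                    {
                        "dyad_id": self.dyad_ids[i],
                        "trial_index": ft.trial_index,
                        "fallback_aoi": table.fallback_aoi,
                        "model_score": score(inferred, actual),
                        "benchmark_score": score(bench, actual),
                    }
                )
        return GazeInferenceResults(self, pd.DataFrame(rows))


class GazeInferenceResults:
    """Cross-validated accuracies of one gaze-inference model.

    Attributes
    ----------
    scores : DataFrame
        One row per (pair, trial): model and benchmark proportion correct.
    pair_means : DataFrame
        Unweighted per-pair means over the four trials.
    grand_mean, benchmark_grand_mean : float
        Unweighted means of the pair means.
    """

    def __init__(self, model: GazeInferenceModel, scores: pd.DataFrame):
        self.model = model
        self.spec = model.spec
        self.scores = scores
        self.pair_means = (
            scores.groupby("dyad_id", sort=True)[["model_score", "benchmark_score"]]
            .mean()
            .reset_index()
        )
        self.grand_mean = float(self.pair_means["model_score"].mean())
        self.benchmark_grand_mean = float(self.pair_means["benchmark_score"].mean())
        n = len(self.pair_means)
        self.se = float(self.pair_means["model_score"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        self.benchmark_se = (
            float(self.pair_means["benchmark_score"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        )
        self.n_pairs = n

    @property
    def advantage(self) -> float:
        """Grand-mean accuracy gain over the majority-class benchmark."""
        return self.grand_mean - self.benchmark_grand_mean

    def summary(self) -> str:
        lines = [
            "Gaze inference: leave-one-pair-out cross-validation",
            "===================================================",
            f"predictor stream : {self.spec.stream}",
            f"predictor source : {self.spec.source}",
            f"window           : +/- {self.spec.half_width_s:g} s at {1/self.spec.step_s:.0f} Hz",
            f"pairs            : {self.n_pairs}",
            "",
            f"{'':<18}{'accuracy':>10}{'SE':>8}",
            f"{'model':<18}{self.grand_mean:>10.3f}{self.se:>8.3f}",
            f"{'benchmark':<18}{self.benchmark_grand_mean:>10.3f}{self.benchmark_se:>8.3f}",
            f"{'advantage':<18}{self.advantage:>10.3f}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<GazeInferenceResults {self.spec.name}: "
            f"model={self.grand_mean:.3f} benchmark={self.benchmark_grand_mean:.3f}>"
        )


def loocv_evaluate(
    sessions, spec: ModelSpec, pooled: bool = False
) -> GazeInferenceResults:
    """Functional shorthand for ``GazeInferenceModel(sessions, spec).fit()``."""
    return GazeInferenceModel(sessions, spec, pooled=pooled).fit()


def evaluate_all_models(sessions) -> dict[str, GazeInferenceResults]:
    """Fit all six (stream, source) models on pre-fused sessions."""
    sessions = [
        fuse_session(s) if isinstance(s, Session) else list(s) for s in sessions
    ]
    return {spec.name: loocv_evaluate(sessions, spec) for spec in ALL_SPECS}
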