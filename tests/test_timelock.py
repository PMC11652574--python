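"""Onset-locked proportion-of-looks curves."""

import numpy as np
import pytest

import dyadgaze as dg
from dyadgaze.data_model import AOI_LABELS
from dyadgaze.errors import EmptyInputError
from dyadgaze.timelock import HALF_STEPS, TAU_GRID, onset_locked_counts

from conftest import make_trial, random_fused_trial


def single_onset_fixture():
    """p1 looks at blocks on [4.5, 5.5) s and model elsewhere; one grab at 5 s."""
    aoi = np.full(300, "model", dtype=object)  # 10 s at 30 Hz
    aoi[135:165] = "blocks"
    trial = make_trial(
        duration_s=10.0,
        aoi_by_participant={"p1": aoi},
        episodes=[("p1", "action", "grab", 5.0, 6.0)],
    )
    return dg.fuse_trial(trial)


class TestExtractOnsets:
    def test_counts_per_episode(self):
        trial = make_trial(
            duration_s=10.0,
            episodes=[
                ("p1", "action", "grab", 1.0, 2.0),
                ("p1", "action", "grab", 3.0, 4.0),
                ("p2", "action", "grab", 5.0, 6.0),
            ],
        )
        onsets = dg.extract_onsets([dg.fuse_trial(trial)], "action", "grab", "own")
        assert len(onsets) == 3

    def test_abutting_episodes_stay_distinct(self):
        trial = make_trial(
            duration_s=10.0,
            episodes=[
                ("p1", "action", "place", 1.0, 2.0),
                ("p1", "action", "place", 2.0, 3.0),
            ],
        )
        onsets = dg.extract_onsets([dg.fuse_trial(trial)], "action", "place", "own")
        assert len(onsets) == 2
        assert [r.onset_idx for r in onsets.records] == [60, 120]

    def test_other_source_swaps_observer(self):
        trial = make_trial(duration_s=10.0, episodes=[("p1", "action", "grab", 1.0, 2.0)])
        fused = dg.fuse_trial(trial)
        own = dg.extract_onsets([fused], "action", "grab", "own")
        other = dg.extract_onsets([fused], "action", "grab", "other")
        assert own.records[0].observer == "p1"
        assert other.records[0].observer == "p2"
        assert own.records[0].onset_idx == other.records[0].onset_idx

    def test_unknown_event_type_rejected(self):
        with pytest.raises(ValueError, match="unknown event type"):
            dg.extract_onsets([], "action", "wave", "own")


class TestCurves:
    def test_hand_enumerated_single_onset(self):
        fused = single_onset_fixture()
        onsets = dg.extract_onsets([fused], "action", "grab", "own")
        curves = dg.timelock_proportions(onsets)
        blocks = curves.curve("blocks")
        model = curves.curve("model")
        inside = (TAU_GRID >= -0.5) & (TAU_GRID < 0.5)
        assert np.all(blocks[inside] == 1.0)
        assert np.all(model[inside] == 0.0)
        assert np.all(model[~inside] == 1.0)

    def test_constant_gaze_degenerate_curves(self):
        trial = make_trial(duration_s=10.0, episodes=[("p1", "action", "grab", 4.0, 5.0)])
        onsets = dg.extract_onsets([dg.fuse_trial(trial)], "action", "grab", "own")
        curves = dg.timelock_proportions(onsets)
        assert np.all(curves.curve("model") == 1.0)
        j = curves.aoi_labels.index("model")
        assert np.all(curves.ci_hi[:, j] - curves.ci_lo[:, j] == 0.0)

    def test_zero_onsets_is_an_error(self):
        trial = make_trial(duration_s=10.0)
        onsets = dg.extract_onsets([dg.fuse_trial(trial)], "action", "grab", "own")
        with pytest.raises(EmptyInputError):
            dg.timelock_proportions(onsets)

    def test_normalization_at_every_tau(self, small_fused):
        flat = [ft for sess in small_fused for ft in sess]
        onsets = dg.extract_onsets(flat, "action", "grab", "own")
        curves = dg.timelock_proportions(onsets)
        sums = curves.mean.sum(axis=1)
        populated = curves.n > 0
        assert np.allclose(sums[populated], 1.0, atol=1e-9)
        assert np.all(curves.ci_lo[populated] <= curves.mean[populated] + 1e-12)
        assert np.all(curves.mean[populated] <= curves.ci_hi[populated] + 1e-12)

    def test_per_tau_instance_counts_vary_near_bounds(self):
        """An onset near the trial start contributes only in-bounds offsets."""
        trial = make_trial(duration_s=10.0, episodes=[("p1", "action", "grab", 1.0, 2.0)])
        onsets = dg.extract_onsets([dg.fuse_trial(trial)], "action", "grab", "own")
        curves = dg.timelock_proportions(onsets)
        assert curves.n[0] == 0  # tau = -3 s falls before t = 0
        assert curves.n[HALF_STEPS] == 1

    def test_shift_equivariance(self):
        """Translating gaze and onsets together leaves curves unchanged."""
        rng = np.random.default_rng(7)
        aoi = np.array(AOI_LABELS, dtype=object)[rng.integers(0, 5, 600)]
        base = make_trial(
            duration_s=20.0,
            aoi_by_participant={"p1": aoi},
            episodes=[("p1", "action", "grab", 8.0, 9.0)],
        )
        delta = 4.0  # whole-sample shift
        shifted_aoi = np.roll(aoi, int(delta * 30))
        shifted = make_trial(
            duration_s=20.0,
            aoi_by_participant={"p1": shifted_aoi},
            episodes=[("p1", "action", "grab", 8.0 + delta, 9.0 + delta)],
        )
        c0 = dg.timelock_proportions(
            dg.extract_onsets([dg.fuse_trial(base)], "action", "grab", "own")
        )
        c1 = dg.timelock_proportions(
            dg.extract_onsets([dg.fuse_trial(shifted)], "action", "grab", "own")
        )
        # compare where both windows are fully inside the trial
        both = (c0.n > 0) & (c1.n > 0)
        assert np.array_equal(c0.mean[both], c1.mean[both])

    def test_oracle_equivalence_with_naive_loop(self):
        """Vectorized counting equals a per-instance Python loop."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            fused = random_fused_trial(rng)
            onsets = dg.extract_onsets([fused], "action", "grab", "own")
            if len(onsets) == 0:
                continue
            counts, n = onset_locked_counts(onsets)
            ref_counts = np.zeros_like(counts)
            ref_n = np.zeros_like(n)
            for r in onsets.records:
                codes = r.trial.aoi[r.observer]
                for k, step in enumerate(range(-HALF_STEPS, HALF_STEPS + 1)):
                    i = r.onset_idx + step
                    if 0 <= i < r.trial.n_samples:
                        ref_counts[k, AOI_LABELS.index(codes[i])] += 1
                        ref_n[k] += 1
            assert np.array_equal(counts, ref_counts)
            assert np.array_equal(n, ref_n)


class TestPeakSummary:
    def test_flat_curve(self):
        trial = make_trial(duration_s=10.0, episodes=[("p1", "action", "grab", 4.0, 5.0)])
        curves = dg.timelock_proportions(
            dg.extract_onsets([dg.fuse_trial(trial)], "action", "grab", "own")
        )
        s = dg.peak_summary(curves, "model")
        assert s.start == s.max == s.min == 1.0

    def test_single_peak_location(self):
        fused = single_onset_fixture()
        curves = dg.timelock_proportions(
            dg.extract_onsets([fused], "action", "grab", "own")
        )
        s = dg.peak_summary(curves, "blocks")
        assert s.max == 1.0
        assert -0.5 <= s.max_tau_s < 0.5
        assert s.min == 0.0

    def test_unknown_aoi_rejected(self):
        fused = single_onset_fixture()
        curves = dg.timelock_proportions(
            dg.extract_onsets([fused], "action", "grab", "own")
        )
        with pytest.raises(ValueError):
            dg.peak_summary(curves, "table")
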