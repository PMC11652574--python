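"""Conditional-probability gaze inference and leave-one-pair-out evaluation."""

import numpy as np
import pandas as pd
import pytest

import dyadgaze as dg
from dyadgaze.data_model import AOI_LABELS, EPISODE_COLUMNS
from dyadgaze.errors import EmptyInputError
from dyadgaze.inference import _argmax_priority

from conftest import brute_force_infer, make_session, make_trial, random_fused_trial, random_table

SPEC_ACTION = dg.ModelSpec("action", "own")


class TestTrainTable:
    def test_degenerate_constant_gaze(self):
        session = make_session(episodes_per_trial=[[("p1", "action", "grab", 2.0, 3.0)]] * 4)
        fused = dg.fuse_session(session)
        table = dg.train_table(fused, SPEC_ACTION)
        assert table.fallback_aoi == "model"
        for t, p in table.probs.items():
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(p[:, AOI_LABELS.index("model")] == 1.0)

    def test_one_instance_table_matches_hand_counts(self):
        aoi = np.full(300, "model", dtype=object)
        aoi[135:165] = "blocks"  # [4.5, 5.5) s
        trial = make_trial(
            duration_s=10.0,
            aoi_by_participant={"p1": aoi},
            episodes=[("p1", "action", "grab", 5.0, 6.0)],
        )
        fused = dg.fuse_trial(trial)
        table = dg.train_table([fused], SPEC_ACTION)
        grab = table.probs["grab"]
        tau = np.arange(-180, 181) / 60.0
        inside = (tau >= -0.5) & (tau < 0.5)
        assert np.all(grab[inside, AOI_LABELS.index("blocks")] == 1.0)
        assert np.all(grab[~inside, AOI_LABELS.index("model")] == 1.0)
        # the other action types have no training instances: marginal fallback
        place = table.probs["place"]
        assert np.allclose(place, np.tile(table.marginal, (361, 1)))

    def test_empty_training_rejected(self):
        with pytest.raises(EmptyInputError):
            dg.train_table([], SPEC_ACTION)


class TestBenchmark:
    def test_modal_aoi(self):
        session = make_session()  # everyone looks at model
        assert dg.benchmark_majority(dg.fuse_session(session)) == "model"

    def test_all_blocks(self):
        aoi = np.full(300, "blocks", dtype=object)
        session = make_session(aoi={"p1": aoi, "p2": aoi.copy()})
        assert dg.benchmark_majority(dg.fuse_session(session)) == "blocks"

    def test_tie_resolved_by_priority(self):
        # exactly half blocks, half build: priority picks build over blocks
        aoi = np.array(["blocks"] * 150 + ["build"] * 150, dtype=object)
        session = make_session(aoi={"p1": aoi, "p2": aoi.copy()})
        assert dg.benchmark_majority(dg.fuse_session(session)) == "build"
        vec = np.array([0.3, 0.3, 0.3, 0.05, 0.05])  # three-way tie
        assert AOI_LABELS[int(_argmax_priority(vec[None, :])[0])] == "model"


class TestInferGaze:
    def test_no_onsets_gives_fallback_everywhere(self):
        fused = dg.fuse_trial(make_trial(duration_s=10.0))
        rng = np.random.default_rng(0)
        table = random_table(rng, SPEC_ACTION)
        out = dg.infer_gaze(table, fused, "p1")
        assert set(out) == {table.fallback_aoi}

    def test_point_mass_table_hand_enumeration(self):
        """blocks|grab point mass, one grab at t=5 -> blocks on [2, 8], fallback
        elsewhere."""
        fused = dg.fuse_trial(
            make_trial(duration_s=10.0, episodes=[("p1", "action", "grab", 5.0, 6.0)])
        )
        rng = np.random.default_rng(1)
        table = random_table(rng, SPEC_ACTION)
        for t in table.probs:
            table.probs[t] = np.zeros((361, 5))
            table.probs[t][:, AOI_LABELS.index("blocks")] = 1.0
        out = dg.infer_gaze(table, fused, "p1")
        t = fused.time_s
        window = (t >= 2.0) & (t <= 8.0)
        assert np.all(out[window] == "blocks")
        assert np.all(out[~window] == table.fallback_aoi)

    def test_overlapping_onsets_average_matches_brute_force(self):
        fused = dg.fuse_trial(
            make_trial(
                duration_s=10.0,
                episodes=[
                    ("p1", "action", "grab", 4.0, 4.5),
                    ("p1", "action", "place", 5.5, 6.0),
                ],
            )
        )
        rng = np.random.default_rng(2)
        table = random_table(rng, SPEC_ACTION)
        out = dg.infer_gaze(table, fused, "p1")
        ref = brute_force_infer(table, fused, "p1", SPEC_ACTION)
        assert np.array_equal(out, ref)

    def test_other_source_uses_partner_onsets(self):
        fused = dg.fuse_trial(
            make_trial(duration_s=10.0, episodes=[("p2", "action", "grab", 5.0, 6.0)])
        )
        rng = np.random.default_rng(3)
        spec = dg.ModelSpec("action", "other")
        table = random_table(rng, spec)
        for t in table.probs:
            table.probs[t] = np.zeros((361, 5))
            table.probs[t][:, AOI_LABELS.index("face")] = 1.0
        out = dg.infer_gaze(table, fused, "p1", spec)
        assert "face" in set(out)  # p2's grab drives p1's inference
        out_p2 = dg.infer_gaze(table, fused, "p2", spec)
        assert set(out_p2) == {table.fallback_aoi}  # p1 made no action

    def test_window_boundary_consistency(self):
        """Samples whose in-window onset set is unchanged keep their label
        when the window is enlarged from 3 to 4 s."""
        rng = np.random.default_rng(4)
        train = random_fused_trial(rng, duration_s=30.0, n_events=8)
        target = random_fused_trial(rng, duration_s=30.0, n_events=8, trial_index=2)
        outs = {}
        for half in (3.0, 4.0):
            spec = dg.ModelSpec("action", "own", half_width_s=half)
            table = dg.train_table([train], spec)
            outs[half] = dg.infer_gaze(table, target, "p1", spec)
        from dyadgaze.timelock import onset_sample_index

        ep = target.episodes
        sub = ep[(ep["stream"] == "action") & (ep["participant"] == "p1")]
        idxs = np.array(
            [
                i
                for _, row in sub.iterrows()
                if (i := onset_sample_index(target, row.onset_s, row.offset_s)) is not None
            ]
        )
        i = np.arange(target.n_samples)
        n_in = lambda h: (np.abs(i[:, None] - idxs[None, :]) <= round(h * 60)).sum(axis=1)
        same_membership = n_in(3.0) == n_in(4.0)
        assert same_membership.any()
        assert np.array_equal(outs[3.0][same_membership], outs[4.0][same_membership])


class TestScore:
    def test_identity_complement_and_half(self):
        a = np.array(["model"] * 4, dtype=object)
        assert dg.score(a, a) == 1.0
        b = np.array(["blocks"] * 4, dtype=object)
        assert dg.score(a, b) == 0.0
        half = np.array(["model", "model", "blocks", "blocks"], dtype=object)
        assert dg.score(a, half) == 0.5
        with pytest.raises(ValueError, match="length mismatch"):
            dg.score(a, a[:2])


class TestLoocv:
    def test_degenerate_all_model_scores_one(self):
        sessions = [make_session(dyad_id=f"d{i:02d}") for i in range(1, 4)]
        res = dg.loocv_evaluate(sessions, SPEC_ACTION)
        assert res.grand_mean == 1.0
        assert res.benchmark_grand_mean == 1.0

    def test_requires_two_sessions(self):
        with pytest.raises(EmptyInputError):
            dg.GazeInferenceModel([make_session()], SPEC_ACTION)

    def test_benchmark_identity(self, small_dataset, small_fused):
        """Held-out benchmark score equals the held-out pair's proportion of
        gaze on the training-modal AOI (exact)."""
        res = dg.loocv_evaluate(small_fused, SPEC_ACTION)
        for i, sess in enumerate(small_fused):
            training = [ft for j, s in enumerate(small_fused) if j != i for ft in s]
            modal = dg.benchmark_majority(training)
            for ft in sess:
                got = res.scores[
                    (res.scores["dyad_id"] == ft.dyad_id)
                    & (res.scores["trial_index"] == ft.trial_index)
                ]["benchmark_score"].iloc[0]
                expected = np.mean(
                    [np.mean(ft.aoi[p] == modal) for p in ft.participants]
                )
                assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_information_collapse(self, small_dataset):
        """With all onsets removed, every model's label series equals the
        benchmark's exactly."""
        stripped = []
        for s in small_dataset:
            fts = []
            for t in s.trials:
                t2 = dg.Trial(
                    dyad_id=t.dyad_id,
                    trial_index=t.trial_index,
                    model_visibility=t.model_visibility,
                    talking=t.talking,
                    duration_s=t.duration_s,
                    gaze=t.gaze,
                    episodes=pd.DataFrame(columns=EPISODE_COLUMNS),
                )
                fts.append(dg.fuse_trial(t2))
            stripped.append(fts)
        for spec in dg.ALL_SPECS:
            res = dg.loocv_evaluate(stripped, spec)
            assert np.allclose(
                res.scores["model_score"], res.scores["benchmark_score"], atol=0
            )

    def test_summary_and_grand_mean_definition(self, small_fused):
        res = dg.loocv_evaluate(small_fused, SPEC_ACTION)
        pair_means = res.scores.groupby("dyad_id")["model_score"].mean()
        assert res.grand_mean == pytest.approx(pair_means.mean())
        text = res.summary()
        assert "benchmark" in text and "action" in text
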