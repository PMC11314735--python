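import numpy as np
import pytest

from ltest.exceptions import NoEventDetectedError, ValidationError
from ltest.segmenter import (
    FeatureCache,
    _participant_folds,
    grid_search_hyperparameters,
    labels_to_transitions,
    predict_labels,
    train_subtask_model,
)
from ltest.subtask_windows import SubtaskDataset


@pytest.fixture(scope="module")
def stand_up_sets(small_cohort):
    from ltest.preprocess import preprocess_trial
    from ltest.subtask_windows import extract_subtask_dataset

    out = []
    for e in small_cohort:
        pt = preprocess_trial(e.trial)
        out.append(extract_subtask_dataset(pt, e.ground_truth, "stand_up"))
    return out


class TestTrainSubtaskModel:
    def test_separable_training_perfect_and_deterministic(self, stand_up_sets):
        cache = FeatureCache(24)
        train, held = stand_up_sets[:-1], stand_up_sets[-1]
        models = [
            train_subtask_model(
                train, "stand_up", n_trees=50, k=10, direction="forward",
                seed=3, cache=cache,
            )
            for _ in range(2)
        ]
        preds = [predict_labels(m, held, cache) for m in models]
        # same seed, same data -> identical predictions on held-out trial
        np.testing.assert_array_equal(preds[0], preds[1])
        # clean synthetic stand-up is separable: training accuracy is perfect
        fit = cache.get(train[0], "forward")
        acc = np.mean(
            models[0].forest.predict(fit.X[models[0].feature_names].to_numpy())
            == fit.y
        )
        assert acc == 1.0

    def test_held_out_prediction_overlaps_ground_truth(self, stand_up_sets):
        cache = FeatureCache(24)
        train, held = stand_up_sets[:-1], stand_up_sets[-1]
        model = train_subtask_model(
            train, "stand_up", n_trees=100, k=10, direction="forward",
            seed=0, cache=cache,
        )
        pred = predict_labels(model, held, cache)
        truth = np.asarray(held.label)
        inter = np.sum((pred == 1) & (truth == 1))
        union = np.sum((pred == 1) | (truth == 1))
        assert inter / union > 0.8  # Jaccard on a clean trial

    def test_empty_training_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            train_subtask_model([], "stand_up", 50, 5, "forward", 0)

    def test_reversed_model_predictions_in_forward_order(self, stand_up_sets):
        cache = FeatureCache(24)
        train, held = stand_up_sets[:-1], stand_up_sets[-1]
        model = train_subtask_model(
            train, "stand_up", n_trees=100, k=10, direction="reversed",
            seed=0, cache=cache,
        )
        pred = predict_labels(model, held, cache)
        assert len(pred) == held.n_samples
        # stand-up sits early in the slice regardless of analysis direction
        first_half = pred[: len(pred) // 2].sum()
        second_half = pred[len(pred) // 2 :].sum()
        assert first_half > second_half


class TestModelPersistence:
    def test_save_load_round_trip(self, stand_up_sets, tmp_path):
        cache = FeatureCache(24)
        train, held = stand_up_sets[:-1], stand_up_sets[-1]
        model = train_subtask_model(
            train, "stand_up", n_trees=50, k=10, direction="forward",
            seed=1, cache=cache,
        )
        path = tmp_path / "stand_up.model.joblib"
        model.save(path)
        from ltest.segmenter import SubtaskModel

        back = SubtaskModel.load(path)
        assert back.feature_names == model.feature_names
        assert back.direction == model.direction
        assert back.n_trees == model.n_trees
        np.testing.assert_array_equal(
            predict_labels(back, held, cache), predict_labels(model, held, cache)
        )


class TestParticipantFolds:
    def test_no_participant_on_both_sides(self):
        participants = ["a", "a", "b", "c", "c", "d", "e"]
        for train_idx, val_idx in _participant_folds(participants, 3, seed=0):
            train_p = {participants[i] for i in train_idx}
            val_p = {participants[i] for i in val_idx}
            assert not train_p & val_p
            assert train_p | val_p == set("abcde")

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValidationError, match="folds"):
            _participant_folds(["a", "b"], 3, seed=0)


class TestGridSearch:
    def test_single_configuration_returned(self, stand_up_sets):
        grid = grid_search_hyperparameters(
            stand_up_sets,
            "stand_up",
            tree_grid=(50,),
            feature_grid=(5,),
            directions=("forward",),
            folds=2,
            seed=0,
        )
        assert grid.best == (50, 5, "forward")
        assert grid.n_configurations == 1

    def test_grid_cardinality_and_enumeration_order_invariance(self, stand_up_sets):
        cache = FeatureCache(24)
        kw = dict(folds=2, seed=0, cache=cache)
        a = grid_search_hyperparameters(
            stand_up_sets, "stand_up",
            tree_grid=(50, 100), feature_grid=(5, 10),
            directions=("forward", "reversed"), **kw,
        )
        b = grid_search_hyperparameters(
            stand_up_sets, "stand_up",
            tree_grid=(100, 50), feature_grid=(10, 5),
            directions=("reversed", "forward"), **kw,
        )
        assert a.n_configurations == 2 * 2 * 2
        assert a.best == b.best
        assert a.scores == pytest.approx(b.scores)

    def test_tie_breaks_toward_smaller_model(self):
        # scores dict path: construct a degenerate search where every config
        # scores identically (constant features force chance-level accuracy)
        rng = np.random.default_rng(0)
        sets = []
        for pid in ("p1", "p2"):
            n = 80
            times = np.arange(n) / 60.0
            label = np.zeros(n, dtype=int)
            label[30:50] = 1
            signals = {
                name: np.zeros(n)
                for name in (
                    "lin_acc_ml", "lin_acc_v", "lin_acc_ap",
                    "gyro_ml", "gyro_v", "gyro_ap", "pitch", "roll", "azimuth",
                )
            }
            sets.append(
                SubtaskDataset(
                    subtask="stand_up", trial_id=f"{pid}_T1", participant_id=pid,
                    i_start=0, i_end=n, times=times, signals=signals, label=label,
                )
            )
        grid = grid_search_hyperparameters(
            sets, "stand_up",
            tree_grid=(100, 50), feature_grid=(10, 5),
            directions=("reversed", "forward"), folds=2, seed=0,
        )
        assert grid.best == (50, 5, "forward")


class TestLabelsToTransitions:
    def test_single_run(self):
        pred = np.array([0, 0, 1, 1, 1, 0])
        times = np.arange(6) / 10.0
        assert labels_to_transitions(pred, times, smoothing=1) == (0.2, 0.4)

    def test_longest_run_wins(self):
        pred = np.array([0, 1, 0, 1, 1, 1, 1, 0])
        times = np.arange(8.0)
        start, end = labels_to_transitions(pred, times, smoothing=1)
        assert (start, end) == (3.0, 6.0)

    def test_tie_goes_to_earliest_run(self):
        pred = np.array([1, 1, 0, 1, 1])
        times = np.arange(5.0)
        assert labels_to_transitions(pred, times, smoothing=1) == (0.0, 1.0)

    def test_median_smoothing_removes_speckle(self):
        # isolated positives vanish; gaps of <= 2 inside a run are bridged
        pred = np.array([1, 0, 0, 0, 0, 1, 1, 0, 1, 1, 0, 0, 0])
        times = np.arange(13.0)
        start, end = labels_to_transitions(pred, times)  # default smoothing 5
        assert (start, end) == (6.0, 8.0)

    def test_all_zero_raises_no_event(self):
        with pytest.raises(NoEventDetectedError):
            labels_to_transitions(np.zeros(10), np.arange(10.0))

    def test_misaligned_rejected(self):
        with pytest.raises(ValidationError):
            labels_to_transitions(np.ones(3), np.arange(4.0))
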