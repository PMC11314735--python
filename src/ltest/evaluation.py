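"""Outcome measures and the leave-one-participant-out harness.

The clinically meaningful criterion is Accuracy_AD: a predicted subtask
boundary counts as correct when its absolute difference from the annotated
time is smaller than that participant's own average step time (mean
interval between consecutive foot strikes).  Sample-level accuracy,
sensitivity and specificity complement it.

Evaluation mirrors the study design: every amputee participant is held out
in turn; the models (including feature ranking and the hyperparameter grid
search) are trained on all able-bodied trials plus the remaining amputee
trials, then segment the held-out trial.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NoEventDetectedError, ValidationError
from .io_model import ManifestEntry, PipelineConfig, SUBTASKS
from .preprocess import preprocess_trial
from .segmenter import (
    FeatureCache,
    grid_search_hyperparameters,
    labels_to_transitions,
    predict_labels,
    train_subtask_model,
)
from .subtask_windows import extract_subtask_dataset


def average_step_time(foot_strikes) -> float:
    """Mean interval between consecutive foot strikes, in seconds."""
    strikes = np.asarray(foot_strikes, dtype=float)
    if len(strikes) < 2:
        raise ValidationError("need at least two foot strikes")
    diffs = np.diff(strikes)
    if np.any(diffs <= 0):
        raise ValidationError("foot strikes must be strictly increasing")
    return float(np.mean(diffs))


def classification_metrics(pred, truth) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of a 0/1 prediction stream.

    Sensitivity/specificity are NaN when the truth lacks the relevant class.
    """
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if len(pred) != len(truth):
        raise ValidationError("prediction and truth lengths differ")
    if len(pred) == 0:
        raise ValidationError("empty series")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    accuracy = (tp + tn) / len(pred)
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    if np.isnan(sensitivity) or np.isnan(specificity):
        warnings.warn("one-class truth: sensitivity/specificity undefined", stacklevel=2)
    return accuracy, sensitivity, specificity


@dataclass
class SegmentationResult:
    """Segmentation of one held-out participant's trial."""

    participant_id: str
    step_time: float  # participant's average step time (s)
    predicted: dict  # subtask -> (start, end) or None if no event detected
    ground_truth: dict  # subtask -> (start, end)
    pred_labels: dict  # subtask -> 0/1 array
    true_labels: dict  # subtask -> 0/1 array
    chosen_configs: dict = field(default_factory=dict)  # subtask -> (trees, k, dir)

    def __post_init__(self) -> None:
        if self.step_time <= 0 or not np.isfinite(self.step_time):
            raise ValidationError("step time must be positive and finite")

    def boundary_error(self, subtask: str, boundary: str) -> float | None:
        """|t_pred - t_gt| for one boundary, or None if no event detected."""
        if self.predicted.get(subtask) is None:
            return None
        idx = 0 if boundary == "start" else 1
        return abs(self.predicted[subtask][idx] - self.ground_truth[subtask][idx])


def accuracy_ad(results, subtask: str, boundary: str) -> float:
    """Percent of participants whose boundary error beats their step time.

    Strict inequality at the threshold; a missing event counts as failure.
    """
    results = list(results)
    if not results:
        raise ValidationError("no results to evaluate")
    if boundary not in ("start", "end"):
        raise ValidationError(f"boundary must be 'start' or 'end', got {boundary!r}")
    hits = 0
    for res in results:
        err = res.boundary_error(subtask, boundary)
        if err is not None and err < res.step_time:
            hits += 1
    return 100.0 * hits / len(results)


@dataclass
class EvaluationReport:
    """Aggregated leave-one-out evaluation in the published table layout."""

    boundary_accuracy: dict  # (subtask, boundary) -> Accuracy_AD %
    subtask_metrics: dict  # subtask -> (accuracy %, sensitivity %, specificity %)
    chosen_configs: dict  # subtask -> modal (n_trees, k, direction)
    n_folds: int = 0
    per_participant: list = field(default_factory=list)  # SegmentationResults
    fold_bookkeeping: list = field(default_factory=list)  # dicts per fold


def aggregate_results(results) -> EvaluationReport:
    """Pool per-participant results into the report tables."""
    results = list(results)
    if not results:
        raise ValidationError("no results to aggregate")
    boundary = {
        (s, b): accuracy_ad(results, s, b)
        for s in SUBTASKS
        for b in ("start", "end")
    }
    metrics = {}
    for s in SUBTASKS:
        pred = np.concatenate([np.asarray(r.pred_labels[s]) for r in results])
        true = np.concatenate([np.asarray(r.true_labels[s]) for r in results])
        acc, sens, spec = classification_metrics(pred, true)
        metrics[s] = (100.0 * acc, 100.0 * sens, 100.0 * spec)
    configs = {}
    for s in SUBTASKS:
        chosen = [tuple(r.chosen_configs[s]) for r in results if s in r.chosen_configs]
        if chosen:
            configs[s] = Counter(chosen).most_common(1)[0][0]
    return EvaluationReport(
        boundary_accuracy=boundary,
        subtask_metrics=metrics,
        chosen_configs=configs,
        n_folds=len(results),
        per_participant=results,
    )


def segment_participant(
    models: dict,
    entry: ManifestEntry,
    config: PipelineConfig,
    cache: FeatureCache | None = None,
) -> SegmentationResult:
    """Apply trained per-subtask models to one participant's trial."""
    cache = cache or FeatureCache(config.window_samples)
    pt = preprocess_trial(entry.trial, config)
    predicted, pred_labels, true_labels, gt_events, chosen = {}, {}, {}, {}, {}
    for subtask in SUBTASKS:
        ds = extract_subtask_dataset(pt, entry.ground_truth, subtask, config.subtask_ranges)
        model = models[subtask]
        pred = predict_labels(model, ds, cache)
        pred_labels[subtask] = pred
        true_labels[subtask] = ds.label
        gt_events[subtask] = entry.ground_truth.event(subtask)
        chosen[subtask] = (model.n_trees, len(model.feature_names), model.direction)
        try:
            predicted[subtask] = labels_to_transitions(pred, ds.times)
        except NoEventDetectedError:
            predicted[subtask] = None
    return SegmentationResult(
        participant_id=entry.participant_id,
        step_time=average_step_time(entry.ground_truth.foot_strikes),
        predicted=predicted,
        ground_truth=gt_events,
        pred_labels=pred_labels,
        true_labels=true_labels,
        chosen_configs=chosen,
    )


def run_loocv(manifest, config: PipelineConfig | None = None) -> EvaluationReport:
    """Leave-one-amputee-out evaluation over a manifest of trials.

    Every fold holds out one amputee participant; training pools all
    able-bodied trials plus the other amputees' trials.  Grid search
    (participant-level folds, feature ranking inside each fold) runs on the
    training set only; the winning configuration is refit on the full
    training set and applied to the held-out trial.
    """
    config = config or PipelineConfig()
    entries = list(manifest)
    amputees = sorted({e.participant_id for e in entries if e.cohort == "amputee"})
    if len(amputees) < 2:
        raise ValidationError("leave-one-out needs at least two amputee participants")

    cache = FeatureCache(config.window_samples)
    # per-trial preprocessing + extraction, shared across folds
    datasets: dict[str, dict] = {}
    for e in entries:
        pt = preprocess_trial(e.trial, config)
        datasets[e.trial.trial_id] = {
            s: extract_subtask_dataset(pt, e.ground_truth, s, config.subtask_ranges)
            for s in SUBTASKS
        }

    results = []
    bookkeeping = []
    for held_out in amputees:
        train_entries = [e for e in entries if e.participant_id != held_out]
        test_entries = [
            e
            for e in entries
            if e.participant_id == held_out and e.cohort == "amputee"
        ]
        train_participants = {e.participant_id for e in train_entries}
        assert held_out not in train_participants
        models = {}
        fold_record = {
            "held_out": held_out,
            "train_participants": sorted(train_participants),
            "grid": {},
        }
        for subtask in SUBTASKS:
            train_ds = [datasets[e.trial.trial_id][subtask] for e in train_entries]
            grid = grid_search_hyperparameters(
                train_ds,
                subtask,
                tree_grid=config.tree_grid,
                feature_grid=config.feature_grid,
                directions=config.directions,
                folds=config.cv_folds,
                seed=config.random_seed,
                window=config.window_samples,
                cache=cache,
                class_weight=config.class_weight,
            )
            models[subtask] = train_subtask_model(
                train_ds,
                subtask,
                n_trees=grid.best_n_trees,
                k=grid.best_k,
                direction=grid.best_direction,
                seed=config.random_seed,
                window=config.window_samples,
                cache=cache,
                class_weight=config.class_weight,
            )
            fold_record["grid"][subtask] = grid.best
        for e in test_entries:
            results.append(segment_participant(models, e, config, cache))
        bookkeeping.append(fold_record)

    report = aggregate_results(results)
    report.fold_bookkeeping = bookkeeping
    return report
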