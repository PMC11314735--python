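"""Per-subtask random-forest classifiers and transition extraction.

One classifier per subtask, trained on pooled per-sample feature rows from
all training trials' subtask datasets.  Hyperparameters — forest size,
number of ANOVA-F-selected features, and analysis direction (forward or
time-reversed) — come from an exhaustive grid search scored by mean k-fold
cross-validated sample accuracy, with folds partitioning *participants* so
no one's samples sit on both sides of a split.  Trees use the Gini
criterion and grow unrestricted until leaves are pure.

Predicted per-sample labels become a (start, end) pair by median-smoothing
the 0/1 stream and taking the longest contiguous run of 1s.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.signal import medfilt
from sklearn.ensemble import RandomForestClassifier

from .exceptions import NoEventDetectedError, ValidationError
from .features import (
    FEATURE_COLUMNS,
    FeatureMatrix,
    anova_f_scores,
    build_feature_matrix,
    select_top_k,
)
from .subtask_windows import SubtaskDataset

#: Width of the median filter applied to prediction streams.
SMOOTHING_SAMPLES = 5


class FeatureCache:
    """Memoizes per-(trial, subtask, direction) feature matrices.

    Feature extraction is a per-trial computation that never sees other
    trials' data, so sharing matrices across cross-validation folds and
    leave-one-out folds is safe (rankings and fits still use training rows
    only).
    """

    def __init__(self, window: int = 24) -> None:
        self.window = window
        self._store: dict[tuple[str, str, str], FeatureMatrix] = {}

    def get(self, ds: SubtaskDataset, direction: str) -> FeatureMatrix:
        key = (ds.trial_id, ds.subtask, direction)
        if key not in self._store:
            self._store[key] = build_feature_matrix(ds, direction, self.window)
        return self._store[key]


@dataclass
class SubtaskModel:
    """A fitted per-subtask classifier plus everything needed to reapply it."""

    subtask: str
    forest: RandomForestClassifier
    feature_names: list[str]
    direction: str
    n_trees: int
    seed: int
    window: int = 24
    training_trials: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.feature_names) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValidationError(f"unknown feature names {sorted(unknown)}")
        if self.direction not in ("forward", "reversed"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "SubtaskModel":
        model = joblib.load(path)
        if not isinstance(model, SubtaskModel):
            raise ValidationError("file does not contain a SubtaskModel")
        return model


@dataclass
class GridSearchResult:
    """All grid-search scores and the winning configuration."""

    scores: dict  # (n_trees, k, direction) -> mean CV accuracy
    best_n_trees: int
    best_k: int
    best_direction: str
    folds: int

    @property
    def best(self) -> tuple[int, int, str]:
        return (self.best_n_trees, self.best_k, self.best_direction)

    @property
    def n_configurations(self) -> int:
        return len(self.scores)


def _pool(matrices: list[FeatureMatrix]) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.concat([m.X for m in matrices], ignore_index=True)
    y = np.concatenate([m.y for m in matrices])
    return X, y


def _make_forest(n_trees: int, seed: int, class_weight=None) -> RandomForestClassifier:
    # Defaults deliberately: Gini criterion, unrestricted depth.
    return RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_depth=None,
        random_state=seed,
        n_jobs=1,
        class_weight=class_weight,
    )


def train_subtask_model(
    datasets: list[SubtaskDataset],
    subtask: str,
    n_trees: int,
    k: int,
    direction: str,
    seed: int,
    window: int = 24,
    cache: FeatureCache | None = None,
    class_weight=None,
) -> SubtaskModel:
    """Fit one subtask's forest on pooled training rows.

    Feature ranking (ANOVA F) runs on the pooled training rows only; the
    top ``k`` features feed the forest.  Deterministic given ``seed``.
    """
    if not datasets:
        raise ValidationError("empty training set")
    if any(ds.subtask != subtask for ds in datasets):
        raise ValidationError("all datasets must belong to the trained subtask")
    cache = cache or FeatureCache(window)
    matrices = [cache.get(ds, direction) for ds in datasets]
    X, y = _pool(matrices)
    if len(np.unique(y)) < 2:
        raise ValidationError("pooled training labels contain a single class")
    ranking = anova_f_scores(X, y)
    names = select_top_k(ranking, k)
    forest = _make_forest(n_trees, seed, class_weight)
    forest.fit(X[names].to_numpy(), y)
    return SubtaskModel(
        subtask=subtask,
        forest=forest,
        feature_names=names,
        direction=direction,
        n_trees=n_trees,
        seed=seed,
        window=window,
        training_trials=tuple(ds.trial_id for ds in datasets),
    )


def _participant_folds(
    participants: list[str], folds: int, seed: int
) -> list[tuple[list[int], list[int]]]:
    """Partition dataset indices into folds by participant."""
    unique = sorted(set(participants))
    if folds > len(unique):
        raise ValidationError(
            f"{folds} folds requested but only {len(unique)} participants available"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique))
    groups = [order[i::folds] for i in range(folds)]
    out = []
    for g in groups:
        held = set(g)
        val_idx = [i for i, p in enumerate(participants) if p in held]
        train_idx = [i for i, p in enumerate(participants) if p not in held]
        out.append((train_idx, val_idx))
    return out


def grid_search_hyperparameters(
    datasets: list[SubtaskDataset],
    subtask: str,
    tree_grid=(50, 100, 250, 500, 750, 1000),
    feature_grid=(5, 10, 15, 25, 50, 75, 82),
    directions=("forward", "reversed"),
    folds: int = 5,
    seed: int = 0,
    window: int = 24,
    cache: FeatureCache | None = None,
    class_weight=None,
) -> GridSearchResult:
    """Exhaustive search over (n_trees, k, direction) by mean CV accuracy.

    Folds split participants.  Within each fold the feature ranking is
    recomputed on that fold's training rows only.  Ties break toward the
    smaller model: fewer trees, then fewer features, then forward.
    """
    if not datasets:
        raise ValidationError("empty training set")
    cache = cache or FeatureCache(window)
    participants = [ds.participant_id for ds in datasets]
    fold_indices = _participant_folds(participants, folds, seed)

    scores: dict[tuple[int, int, str], list[float]] = {
        (t, k, d): []
        for t, k, d in itertools.product(tree_grid, feature_grid, directions)
    }
    for train_idx, val_idx in fold_indices:
        if not train_idx or not val_idx:
            continue
        for direction in directions:
            train_m = [cache.get(datasets[i], direction) for i in train_idx]
            val_m = [cache.get(datasets[i], direction) for i in val_idx]
            X_tr, y_tr = _pool(train_m)
            X_va, y_va = _pool(val_m)
            if len(np.unique(y_tr)) < 2:
                continue
            ranking = anova_f_scores(X_tr, y_tr)
            for k in feature_grid:
                names = select_top_k(ranking, k)
                A_tr = X_tr[names].to_numpy()
                A_va = X_va[names].to_numpy()
                for n_trees in tree_grid:
                    forest = _make_forest(n_trees, seed, class_weight)
                    forest.fit(A_tr, y_tr)
                    acc = float(np.mean(forest.predict(A_va) == y_va))
                    scores[(n_trees, k, direction)].append(acc)

    mean_scores = {
        cfg: (float(np.mean(v)) if v else float("-inf")) for cfg, v in scores.items()
    }
    # argmax with deterministic tie-break: fewer trees, fewer features, forward
    best = max(
        mean_scores,
        key=lambda cfg: (
            mean_scores[cfg],
            -cfg[0],
            -cfg[1],
            cfg[2] == "forward",
        ),
    )
    return GridSearchResult(
        scores=mean_scores,
        best_n_trees=best[0],
        best_k=best[1],
        best_direction=best[2],
        folds=folds,
    )


def predict_labels(model: SubtaskModel, ds: SubtaskDataset, cache: FeatureCache | None = None) -> np.ndarray:
    """Per-sample 0/1 predictions in forward sample order."""
    cache = cache or FeatureCache(model.window)
    fm = cache.get(ds, model.direction)
    pred = model.forest.predict(fm.X[model.feature_names].to_numpy()).astype(np.int8)
    if model.direction == "reversed":
        pred = pred[::-1]
    return pred


def labels_to_transitions(
    pred: np.ndarray, times: np.ndarray, smoothing: int = SMOOTHING_SAMPLES
) -> tuple[float, float]:
    """(start, end) times of the longest predicted run after median smoothing.

    Ties go to the earliest run.  Raises NoEventDetectedError if smoothing
    leaves no positive samples.
    """
    pred = np.asarray(pred).astype(float)
    times = np.asarray(times, dtype=float)
    if len(pred) == 0 or len(pred) != len(times):
        raise ValidationError("predictions and times must be nonempty and aligned")
    smooth = medfilt(pred, smoothing) if len(pred) >= smoothing else pred
    lab = (smooth > 0.5).astype(int)
    edges = np.diff(np.concatenate(([0], lab, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    if len(starts) == 0:
        raise NoEventDetectedError("no positive run after smoothing")
    lengths = ends - starts
    i = int(np.argmax(lengths))  # argmax takes the earliest maximal run
    return float(times[starts[i]]), float(times[ends[i]])
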