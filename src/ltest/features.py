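"""Windowed feature extraction and ANOVA-F feature ranking.

For every sample of a subtask dataset, eight statistics (mean, standard
deviation, variation, max, min, range, kurtosis, skewness) are computed over
a trailing window — 24 samples (0.4 s at 60 Hz) by default — for each of the
nine sensor signals, giving 72 windowed features.  The nine instantaneous
signal values and system time complete the canonical 82-column matrix.

Conventions: "variation" is the sample variance (n-1 denominator) and
"std" its square root; skewness and kurtosis are the standardized third and
fourth central moments with kurtosis reported as excess (a normal window
scores 0); a constant window scores 0 on all dispersion and shape
statistics.  Rows before the first full window repeat the first full-window
values so every labeled sample keeps a feature row (the stand-up subtask
begins at sample 0 and must remain classifiable).

A reversed analysis direction mirrors the dataset in time before windowing:
for subtasks near the end of the trial the informative context then lies
*ahead* of each sample instead of behind it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.feature_selection import f_classif

from .exceptions import ValidationError
from .io_model import SIGNAL_COLUMNS
from .subtask_windows import SubtaskDataset

STAT_NAMES: tuple[str, ...] = (
    "mean",
    "std",
    "variation",
    "max",
    "min",
    "range",
    "kurtosis",
    "skewness",
)

#: Canonical 82-column feature schema: 9 signals x 8 window statistics,
#: the 9 instantaneous signal values, and system time.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{sig}_{stat}" for sig in SIGNAL_COLUMNS for stat in STAT_NAMES
) + SIGNAL_COLUMNS + ("system_time",)

N_FEATURES = len(FEATURE_COLUMNS)  # 82


def window_statistics(signal: np.ndarray, window: int = 24) -> dict[str, np.ndarray]:
    """Trailing-window statistics, one value per input sample.

    The window ending at sample ``i`` covers ``[i - window + 1, i]``; the
    first ``window - 1`` rows repeat the first full-window values.
    """
    x = np.asarray(signal, dtype=float)
    if window < 2:
        raise ValidationError("window must be >= 2")
    if len(x) < window:
        raise ValidationError(
            f"series of length {len(x)} shorter than window {window}"
        )
    w = sliding_window_view(x, window)  # (n - window + 1, window)
    mean = w.mean(axis=1)
    dev = w - mean[:, None]
    m2 = np.mean(dev**2, axis=1)  # population second moment
    var = np.sum(dev**2, axis=1) / (window - 1)  # sample variance
    std = np.sqrt(var)
    mx = w.max(axis=1)
    mn = w.min(axis=1)
    constant = m2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(constant, 0.0, np.mean(dev**3, axis=1) / m2**1.5)
        kurt = np.where(constant, 0.0, np.mean(dev**4, axis=1) / m2**2 - 3.0)
    stats = {
        "mean": mean,
        "std": std,
        "variation": var,
        "max": mx,
        "min": mn,
        "range": mx - mn,
        "kurtosis": kurt,
        "skewness": skew,
    }
    pad = window - 1
    return {k: np.concatenate([np.full(pad, v[0]), v]) for k, v in stats.items()}


def reverse_dataset(ds: SubtaskDataset) -> SubtaskDataset:
    """Mirror a subtask dataset in time.

    Signals and labels reverse in sample order; the time column is
    re-reflected about the slice midpoint (t'_i = t_0 + t_last - t_{n-1-i})
    so it stays strictly increasing and the operation is an involution.
    The direction flag flips.
    """
    t = ds.times
    new_times = t[0] + t[-1] - t[::-1]
    return replace(
        ds,
        times=new_times,
        signals={k: v[::-1].copy() for k, v in ds.signals.items()},
        label=ds.label[::-1].copy(),
        direction="reversed" if ds.direction == "forward" else "forward",
    )


@dataclass
class FeatureMatrix:
    """Per-sample feature table aligned with the subtask labels."""

    X: pd.DataFrame  # 82 canonical columns
    y: np.ndarray
    direction: str
    subtask: str
    trial_id: str
    participant_id: str

    def __post_init__(self) -> None:
        if tuple(self.X.columns) != FEATURE_COLUMNS:
            raise ValidationError("feature matrix must carry the canonical 82 columns")
        if len(self.X) != len(self.y):
            raise ValidationError("feature rows and labels must align")

    @property
    def n_samples(self) -> int:
        return len(self.X)


def build_feature_matrix(
    ds: SubtaskDataset,
    direction: str = "forward",
    window: int = 24,
) -> FeatureMatrix:
    """Assemble the 82-column matrix for one subtask dataset.

    ``direction="reversed"`` mirrors the dataset before windowing; rows of
    the result are then in reversed chronological order.
    """
    if direction not in ("forward", "reversed"):
        raise ValidationError(f"unknown direction {direction!r}")
    if direction == "reversed":
        ds = reverse_dataset(ds)
    cols: dict[str, np.ndarray] = {}
    for sig in SIGNAL_COLUMNS:
        stats = window_statistics(ds.signals[sig], window)
        for stat in STAT_NAMES:
            cols[f"{sig}_{stat}"] = stats[stat]
    for sig in SIGNAL_COLUMNS:
        cols[sig] = np.asarray(ds.signals[sig], dtype=float)
    cols["system_time"] = np.asarray(ds.times, dtype=float)
    X = pd.DataFrame(cols, columns=list(FEATURE_COLUMNS))
    return FeatureMatrix(
        X=X,
        y=np.asarray(ds.label).astype(int),
        direction=direction,
        subtask=ds.subtask,
        trial_id=ds.trial_id,
        participant_id=ds.participant_id,
    )


@dataclass
class FeatureRanking:
    """Features ordered by decreasing ANOVA F score."""

    names: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != len(self.scores):
            raise ValidationError("names and scores must align")
        if np.any(~np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValidationError("scores must be finite and non-negative")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return select_top_k(self, k)


def anova_f_scores(X: pd.DataFrame, y: np.ndarray) -> FeatureRanking:
    """Rank features by the one-way (two-group) ANOVA F statistic.

    F = MS_between / MS_within with (1, n-2) degrees of freedom for a binary
    label.  Constant features score 0 (with a warning).  Ties keep the
    original column order (stable sort).
    """
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("labels must contain both classes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features raise divide warnings
        scores, _ = f_classif(X.to_numpy(), y)
    scores = np.asarray(scores, dtype=float)
    bad = ~np.isfinite(scores)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} constant or degenerate feature(s) scored 0",
            stacklevel=2,
        )
        scores = np.where(bad, 0.0, scores)
    scores = np.clip(scores, 0.0, None)
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(
        names=[X.columns[i] for i in order],
        scores=scores[order],
    )


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """The ``k`` highest-scoring feature names, ranked order preserved."""
    if not 1 <= k <= len(ranking.names):
        raise ValidationError(
            f"k={k} outside valid range [1, {len(ranking.names)}]"
        )
    return list(ranking.names[:k])
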