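"""Per-subtask data-range extraction and binary occurrence labels.

Each of the six subtask classifiers only ever sees the portion of a trial
where its subtask can plausibly occur — a percent range of the trial length
observed across a reference cohort (e.g. stand-up within the first 31%).
This trims the heavy class imbalance a whole-trial labeling would carry.
The extracted slice keeps system time plus the nine conditioned signals and
gains an 11th column: the per-sample 0/1 indicator that the subtask is
occurring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import RangeCoverageError, ValidationError
from .io_model import DEFAULT_SUBTASK_RANGES, SIGNAL_COLUMNS, SUBTASKS, GroundTruth
from .preprocess import PreprocessedTrial


@dataclass
class SubtaskDataset:
    """One trial's slice for one subtask, with the occurrence label."""

    subtask: str
    trial_id: str
    participant_id: str
    i_start: int  # slice bounds in trial sample indices, half-open
    i_end: int
    times: np.ndarray
    signals: dict  # channel name -> sliced series
    label: np.ndarray  # 0/1 per sample
    direction: str = "forward"

    def __post_init__(self) -> None:
        n = len(self.times)
        if any(len(v) != n for v in self.signals.values()) or len(self.label) != n:
            raise ValidationError("subtask dataset columns must share one length")
        runs = _count_runs(self.label)
        if runs != 1:
            raise ValidationError(
                f"label must be a single contiguous run of 1s (found {runs})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        """The 11-column table: system time, nine signals, label."""
        data = {"time_s": self.times}
        for name in SIGNAL_COLUMNS:
            data[name] = self.signals[name]
        data["label"] = self.label
        return pd.DataFrame(data)


def _count_runs(label: np.ndarray) -> int:
    lab = np.asarray(label).astype(int)
    d = np.diff(np.concatenate(([0], lab, [0])))
    return int(np.sum(d == 1))


def encode_subtask_labels(times: np.ndarray, event: tuple[float, float]) -> np.ndarray:
    """0/1 occurrence vector: 1 where start <= t <= end (inclusive both ends)."""
    times = np.asarray(times, dtype=float)
    start, end = float(event[0]), float(event[1])
    if not start < end:
        raise ValidationError("event start must precede end")
    label = ((times >= start) & (times <= end)).astype(np.int8)
    if label.sum() == 0:
        raise ValidationError(
            f"event ({start:.3f}, {end:.3f}) does not overlap the slice "
            f"[{times[0]:.3f}, {times[-1]:.3f}]"
        )
    if label.all():
        warnings.warn(
            "subtask spans the entire slice; the classifier has no negative "
            "examples from this trial",
            stacklevel=2,
        )
    return label


def slice_bounds(n_samples: int, pct_range: tuple[float, float]) -> tuple[int, int]:
    """Half-open index bounds for a percent range, rounded outward."""
    lo_pct, hi_pct = pct_range
    i0 = max(0, math.floor(lo_pct * n_samples / 100.0))
    i1 = min(n_samples, math.ceil(hi_pct * n_samples / 100.0))
    return i0, i1


def extract_subtask_dataset(
    trial: PreprocessedTrial,
    gt: GroundTruth,
    subtask: str,
    ranges: dict | None = None,
) -> SubtaskDataset:
    """Slice the subtask's percent range out of a conditioned trial.

    Raises RangeCoverageError if the ground-truth interval escapes the
    configured range — a sign the range table is too tight for this cohort.
    """
    if subtask not in SUBTASKS:
        raise ValidationError(f"unknown subtask {subtask!r}")
    ranges = ranges or DEFAULT_SUBTASK_RANGES
    n = trial.n_samples
    i0, i1 = slice_bounds(n, ranges[subtask])
    times = trial.sample_times[i0:i1]
    start, end = gt.event(subtask)
    # Half-sample slack: an event annotated at the exact trial end falls
    # between the last sample and the nominal duration.
    half_dt = 0.5 * float(np.median(np.diff(trial.sample_times)))
    if not (times[0] - half_dt <= start and end <= times[-1] + half_dt):
        raise RangeCoverageError(
            f"{subtask}: ground truth ({start:.3f}, {end:.3f}) not contained in "
            f"range slice [{times[0]:.3f}, {times[-1]:.3f}] "
            f"({ranges[subtask][0]:.0f}-{ranges[subtask][1]:.0f}% of trial)"
        )
    label = encode_subtask_labels(times, (start, end))
    signals = {name: trial.signal(name)[i0:i1] for name in SIGNAL_COLUMNS}
    return SubtaskDataset(
        subtask=subtask,
        trial_id=trial.trial_id,
        participant_id=trial.participant_id,
        i_start=i0,
        i_end=i1,
        times=times,
        signals=signals,
        label=label,
    )


def extract_all_subtasks(
    trial: PreprocessedTrial,
    gt: GroundTruth,
    ranges: dict | None = None,
) -> dict[str, SubtaskDataset]:
    """The six per-subtask datasets of one trial."""
    return {s: extract_subtask_dataset(trial, gt, s, ranges) for s in SUBTASKS}
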