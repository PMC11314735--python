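"""Trial and ground-truth data model, file dialects, and pipeline configuration.

A trial is a single L test recording from a waist-worn smartphone IMU:
nine sensor channels (three linear-acceleration axes, three angular-velocity
axes, pitch, roll, azimuth) sampled nominally at 60 Hz, plus system time.
Ground truth is a sidecar annotation holding the start/end time of each of
the six subtasks (stand-up, two 90-degree turns, two 180-degree turns,
sit-down) and the foot-strike times used to derive per-participant step time.

Axis convention: X = mediolateral, Y = vertical, Z = anteroposterior, so
turning appears as rotation about the vertical (Y) gyroscope axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

#: The six L test subtasks, in circuit order.
SUBTASKS: tuple[str, ...] = (
    "stand_up",
    "turn90_1",
    "turn180_1",
    "turn90_2",
    "turn180_2",
    "sit_down",
)

#: The nine sensor channels (internal names, deg / deg/s / m/s^2 units).
SIGNAL_COLUMNS: tuple[str, ...] = (
    "lin_acc_ml",
    "lin_acc_v",
    "lin_acc_ap",
    "gyro_ml",
    "gyro_v",
    "gyro_ap",
    "pitch",
    "roll",
    "azimuth",
)

#: CSV header names for trial files, keyed by internal channel name.
CSV_COLUMN_MAP: dict[str, str] = {
    "time_s": "time_s",
    "lin_acc_ml": "lin_acc_ml",
    "lin_acc_v": "lin_acc_v",
    "lin_acc_ap": "lin_acc_ap",
    "gyro_ml": "gyro_ml",
    "gyro_v": "gyro_v",
    "gyro_ap": "gyro_ap",
    "pitch": "pitch_deg",
    "roll": "roll_deg",
    "azimuth": "azimuth_deg",
}

#: Default subtask data ranges as (earliest %, latest %) of trial length.
#: These are the earliest/latest occurrences observed across a mixed
#: able-bodied + amputee cohort and deliberately over-cover each subtask.
DEFAULT_SUBTASK_RANGES: dict[str, tuple[float, float]] = {
    "stand_up": (0.0, 31.0),
    "turn90_1": (10.0, 42.0),
    "turn180_1": (36.0, 63.0),
    "turn90_2": (61.0, 84.0),
    "turn180_2": (72.0, 97.0),
    "sit_down": (76.0, 100.0),
}

DEFAULT_TREE_GRID: tuple[int, ...] = (50, 100, 250, 500, 750, 1000)
DEFAULT_FEATURE_GRID: tuple[int, ...] = (5, 10, 15, 25, 50, 75, 82)
DIRECTIONS: tuple[str, ...] = ("forward", "reversed")


@dataclass
class PipelineConfig:
    """Scalar constants of the pipeline, with the published defaults."""

    sample_rate_hz: float = 60.0
    azimuth_jump_threshold_deg: float = 10.0
    azimuth_correction_mode: str = "unwrap"  # "unwrap" | "literal"
    filter_order: int = 4
    filter_cutoff_hz: float = 4.0
    window_samples: int = 24
    subtask_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTASK_RANGES)
    )
    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID
    feature_grid: tuple[int, ...] = DEFAULT_FEATURE_GRID
    directions: tuple[str, ...] = DIRECTIONS
    cv_folds: int = 5
    class_weight: str | None = None  # passed through to the forest
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.azimuth_jump_threshold_deg <= 0:
            raise ValidationError("azimuth_jump_threshold_deg must be positive")
        if self.azimuth_correction_mode not in ("unwrap", "literal"):
            raise ValidationError(
                "azimuth_correction_mode must be 'unwrap' or 'literal'"
            )
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")
        if not 0 < self.filter_cutoff_hz < self.sample_rate_hz / 2:
            raise ValidationError("filter_cutoff_hz must lie in (0, Nyquist)")
        if self.window_samples < 2:
            raise ValidationError("window_samples must be >= 2")
        if set(self.subtask_ranges) != set(SUBTASKS):
            raise ValidationError("subtask_ranges must cover exactly the six subtasks")
        for name, (lo, hi) in self.subtask_ranges.items():
            if not (0 <= lo < hi <= 100):
                raise ValidationError(
                    f"subtask range for {name!r} must satisfy 0 <= earliest < latest <= 100"
                )
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        self.tree_grid = tuple(int(t) for t in self.tree_grid)
        self.feature_grid = tuple(int(k) for k in self.feature_grid)
        self.directions = tuple(self.directions)
        if any(t < 1 for t in self.tree_grid):
            raise ValidationError("tree_grid entries must be >= 1")
        if any(k < 1 for k in self.feature_grid):
            raise ValidationError("feature_grid entries must be >= 1")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValidationError(f"unknown direction {d!r}")

    @property
    def window_seconds(self) -> float:
        return self.window_samples / self.sample_rate_hz

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subtask_ranges"] = {k: list(v) for k, v in d["subtask_ranges"].items()}
        d["tree_grid"] = list(d["tree_grid"])
        d["feature_grid"] = list(d["feature_grid"])
        d["directions"] = list(d["directions"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "subtask_ranges" in d:
            d["subtask_ranges"] = {
                k: tuple(v) for k, v in d["subtask_ranges"].items()
            }
        for key in ("tree_grid", "feature_grid", "directions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class IMUTrial:
    """One trial's time-aligned ten-channel signal record."""

    trial_id: str
    participant_id: str
    cohort: str  # "able_bodied" | "amputee"
    sample_times: np.ndarray  # seconds from recording start
    lin_acc_ml: np.ndarray
    lin_acc_v: np.ndarray
    lin_acc_ap: np.ndarray
    gyro_ml: np.ndarray
    gyro_v: np.ndarray
    gyro_ap: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    azimuth: np.ndarray  # raw heading, wrapped into [0, 360)
    sample_rate_hz: float = 60.0

    MIN_SAMPLES = 48  # two full feature windows

    def __post_init__(self) -> None:
        for name in ("sample_times", *SIGNAL_COLUMNS):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_times)

    def channel(self, name: str) -> np.ndarray:
        if name not in SIGNAL_COLUMNS:
            raise KeyError(name)
        return getattr(self, name)

    def validate(self) -> None:
        if self.cohort not in ("able_bodied", "amputee"):
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        n = len(self.sample_times)
        if n < self.MIN_SAMPLES:
            raise ValidationError(
                f"trial {self.trial_id!r} has {n} samples; need >= {self.MIN_SAMPLES}"
            )
        for name in SIGNAL_COLUMNS:
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"channel {name!r} length differs from sample_times"
                )
        dt = np.diff(self.sample_times)
        if np.any(dt <= 0):
            raise ValidationError("sample_times must be strictly increasing")
        nominal = 1.0 / self.sample_rate_hz
        med = float(np.median(dt))
        if not (0.8 * nominal <= med <= 1.2 * nominal):
            raise ValidationError(
                f"median sample interval {med:.4f}s deviates >20% from nominal {nominal:.4f}s"
            )
        if np.any(self.azimuth < 0) or np.any(self.azimuth >= 360):
            raise ValidationError("raw azimuth values must lie in [0, 360)")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.sample_times}
        for name in SIGNAL_COLUMNS:
            data[CSV_COLUMN_MAP[name]] = getattr(self, name)
        return pd.DataFrame(data)


@dataclass
class GroundTruth:
    """Per-trial subtask intervals and foot-strike times (seconds)."""

    trial_id: str
    subtask_events: dict[str, tuple[float, float]]
    foot_strikes: np.ndarray
    total_time: float

    def __post_init__(self) -> None:
        self.foot_strikes = np.asarray(self.foot_strikes, dtype=float)
        self.subtask_events = {
            k: (float(v[0]), float(v[1])) for k, v in self.subtask_events.items()
        }
        self.validate()

    def validate(self) -> None:
        missing = set(SUBTASKS) - set(self.subtask_events)
        if missing:
            raise ValidationError(f"missing subtask events: {sorted(missing)}")
        for name, (start, end) in self.subtask_events.items():
            if not start < end:
                raise ValidationError(f"subtask {name!r}: start must precede end")
        starts = [self.subtask_events[name][0] for name in SUBTASKS]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValidationError("subtask starts must follow L test circuit order")
        if len(self.foot_strikes) < 2:
            raise ValidationError("need at least two foot strikes")
        if np.any(np.diff(self.foot_strikes) <= 0):
            raise ValidationError("foot strikes must be strictly increasing")
        if self.total_time <= 0:
            raise ValidationError("total_time must be positive")

    def event(self, subtask: str) -> tuple[float, float]:
        return self.subtask_events[subtask]


def read_trial(
    path: str | Path,
    config: PipelineConfig | None = None,
    *,
    trial_id: str | None = None,
    participant_id: str = "unknown",
    cohort: str = "amputee",
) -> IMUTrial:
    """Read a trial CSV (header-driven; column order immaterial)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for internal, column in CSV_COLUMN_MAP.items():
        if column not in df.columns:
            raise FormatError(f"trial file {path.name} missing column {column!r}")
    sample_rate = config.sample_rate_hz if config is not None else 60.0
    return IMUTrial(
        trial_id=trial_id or path.stem,
        participant_id=participant_id,
        cohort=cohort,
        sample_times=df["time_s"].to_numpy(),
        **{
            name: df[CSV_COLUMN_MAP[name]].to_numpy()
            for name in SIGNAL_COLUMNS
        },
        sample_rate_hz=sample_rate,
    )


def write_trial(trial: IMUTrial, path: str | Path) -> None:
    trial.to_frame().to_csv(path, index=False, float_format="%.9f")


def read_ground_truth(path: str | Path, trial_id: str | None = None) -> GroundTruth:
    """Read a ground-truth sidecar (YAML: subtasks.<name>.start/end, foot_strikes)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "subtasks" not in data:
        raise FormatError(f"ground-truth file {path.name} missing 'subtasks' section")
    events = {}
    for name, rec in data["subtasks"].items():
        try:
            events[name] = (float(rec["start"]), float(rec["end"]))
        except (KeyError, TypeError) as exc:
            raise FormatError(
                f"ground-truth subtask {name!r} needs start/end"
            ) from exc
    if "foot_strikes" not in data:
        raise FormatError(f"ground-truth file {path.name} missing 'foot_strikes'")
    return GroundTruth(
        trial_id=trial_id or data.get("trial_id", path.stem),
        subtask_events=events,
        foot_strikes=np.asarray(data["foot_strikes"], dtype=float),
        total_time=float(data.get("total_time", max(e for _, e in events.values()))),
    )


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    data = {
        "trial_id": gt.trial_id,
        "total_time": float(gt.total_time),
        "subtasks": {
            name: {"start": float(s), "end": float(e)}
            for name, (s, e) in gt.subtask_events.items()
        },
        "foot_strikes": [float(t) for t in gt.foot_strikes],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class ManifestEntry:
    """One trial plus its annotation and provenance."""

    trial: IMUTrial
    ground_truth: GroundTruth
    participant_id: str
    cohort: str  # "able_bodied" | "amputee"


def load_manifest(path: str | Path, config: PipelineConfig | None = None) -> list[ManifestEntry]:
    """Load a YAML manifest listing trial/ground-truth paths with participant ids.

    Schema: ``trials: [{trial: p.csv, ground_truth: p.gt.yaml,
    participant_id: ..., cohort: ...}, ...]``; relative paths resolve
    against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "trials" not in data:
        raise FormatError(f"manifest {path.name} missing 'trials' list")
    entries = []
    for rec in data["trials"]:
        for key in ("trial", "ground_truth", "participant_id", "cohort"):
            if key not in rec:
                raise FormatError(f"manifest entry missing key {key!r}")
        trial_path = path.parent / rec["trial"]
        gt_path = path.parent / rec["ground_truth"]
        trial = read_trial(
            trial_path,
            config,
            participant_id=rec["participant_id"],
            cohort=rec["cohort"],
        )
        gt = read_ground_truth(gt_path, trial_id=trial.trial_id)
        entries.append(
            ManifestEntry(
                trial=trial,
                ground_truth=gt,
                participant_id=rec["participant_id"],
                cohort=rec["cohort"],
            )
        )
    return entries


def write_manifest(entries: Sequence[ManifestEntry], out_dir: str | Path) -> Path:
    """Write trial CSVs, ground-truth sidecars, and a manifest YAML to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for entry in entries:
        trial_name = f"{entry.trial.trial_id}.csv"
        gt_name = f"{entry.trial.trial_id}.gt.yaml"
        write_trial(entry.trial, out_dir / trial_name)
        write_ground_truth(entry.ground_truth, out_dir / gt_name)
        records.append(
            {
                "trial": trial_name,
                "ground_truth": gt_name,
                "participant_id": entry.participant_id,
                "cohort": entry.cohort,
            }
        )
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"trials": records}, fh, sort_keys=False)
    return manifest_path


# --- segmentation report dialect -------------------------------------------

REPORT_COLUMNS = (
    "kind",
    "subtask",
    "boundary",
    "accuracy_ad_pct",
    "accuracy_pct",
    "sensitivity_pct",
    "specificity_pct",
    "n_trees",
    "n_features",
    "direction",
)


def write_evaluation_report(report, path: str | Path) -> None:
    """Write an EvaluationReport as a flat CSV.

    One ``boundary`` row per subtask boundary (12) carrying its Accuracy_AD,
    and one ``metrics`` row per subtask (6) carrying pooled sample-level
    accuracy / sensitivity / specificity.  Percentages are validated to
    [0, 100] (NaN allowed for undefined metrics).
    """
    rows = []
    for subtask in SUBTASKS:
        for boundary in ("start", "end"):
            acc_ad = report.boundary_accuracy[(subtask, boundary)]
            _check_pct(acc_ad, f"Accuracy_AD[{subtask},{boundary}]")
            cfg = report.chosen_configs.get(subtask)
            rows.append(
                {
                    "kind": "boundary",
                    "subtask": subtask,
                    "boundary": boundary,
                    "accuracy_ad_pct": acc_ad,
                    "n_trees": cfg[0] if cfg else "",
                    "n_features": cfg[1] if cfg else "",
                    "direction": cfg[2] if cfg else "",
                }
            )
    for subtask in SUBTASKS:
        acc, sens, spec = report.subtask_metrics[subtask]
        for val, label in ((acc, "accuracy"), (sens, "sensitivity"), (spec, "specificity")):
            _check_pct(val, f"{label}[{subtask}]", allow_nan=True)
        rows.append(
            {
                "kind": "metrics",
                "subtask": subtask,
                "accuracy_pct": acc,
                "sensitivity_pct": sens,
                "specificity_pct": spec,
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)


def _check_pct(value: float, label: str, allow_nan: bool = False) -> None:
    if value is None or (allow_nan and np.isnan(value)):
        return
    if not 0.0 <= float(value) <= 100.0:
        raise ValidationError(f"{label} = {value!r} outside [0, 100]")


def write_segmentation_report(results: Iterable, path: str | Path):
    """Aggregate per-participant segmentation results and write the report CSV.

    Returns the aggregated EvaluationReport.
    """
    from .evaluation import aggregate_results  # late import; avoids a cycle

    results = list(results)
    if not results:
        raise ValidationError("cannot write a report from zero results")
    report = aggregate_results(results)
    write_evaluation_report(report, path)
    return report


def read_segmentation_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"report missing columns {sorted(missing)}")
    return df
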