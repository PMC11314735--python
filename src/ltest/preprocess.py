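"""Signal conditioning before feature extraction.

Four operations: azimuth discontinuity correction (the heading sensor wraps
at the 0/360 degree boundary, which shreds turn signatures if left alone),
zero-lag Butterworth low-pass filtering of acceleration and angular-velocity
channels, per-trial magnitude normalization, and video-alignment time
offsets.  Pitch, roll and azimuth are left unfiltered: they are already
smooth orientation estimates and filtering them would soften the sharp turn
onsets the segmenter keys on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import ValidationError
from .io_model import IMUTrial, PipelineConfig, SIGNAL_COLUMNS

#: Channels that receive low-pass filtering and magnitude normalization.
FILTERED_CHANNELS = ("lin_acc_ml", "lin_acc_v", "lin_acc_ap", "gyro_ml", "gyro_v", "gyro_ap")


def correct_azimuth(
    azimuth: np.ndarray,
    threshold_deg: float = 10.0,
    mode: str = "unwrap",
) -> np.ndarray:
    """Remove 0/360 wrap discontinuities from a heading series.

    Consecutive differences with magnitude above ``threshold_deg`` are treated
    as wrap artifacts.  In ``unwrap`` mode (default) each such jump is reduced
    modulo 360 to its nearest equivalent, preserving genuine within-sample
    rotation; in ``literal`` mode the jump is removed entirely (the historical
    threshold-subtraction rule).  The output is continuous and unbounded.
    """
    az = np.asarray(azimuth, dtype=float)
    if az.ndim != 1 or len(az) < 2:
        raise ValidationError("azimuth series must be 1-D with at least 2 samples")
    if threshold_deg <= 0:
        raise ValidationError("threshold must be positive")
    d = np.diff(az)
    jumped = np.abs(d) > threshold_deg
    if mode == "unwrap":
        d = np.where(jumped, d - 360.0 * np.round(d / 360.0), d)
    elif mode == "literal":
        d = np.where(jumped, 0.0, d)
    else:
        raise ValidationError(f"unknown azimuth correction mode {mode!r}")
    out = np.empty_like(az)
    out[0] = az[0]
    np.cumsum(d, out=out[1:])
    out[1:] += az[0]
    return out


def lowpass_zero_lag(
    signal: np.ndarray,
    order: int = 4,
    cutoff_hz: float = 4.0,
    sample_rate_hz: float = 60.0,
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase, DC gain 1).

    The effective magnitude response is the squared single-pass response
    |H(f)|^2; event timing is preserved because the backward pass cancels
    the phase of the forward pass.  Edges are reflect-padded with
    ``3 * order`` samples.
    """
    x = np.asarray(signal, dtype=float)
    if not 0 < cutoff_hz < sample_rate_hz / 2:
        raise ValidationError("cutoff must lie strictly below the Nyquist frequency")
    padlen = 3 * order
    if len(x) <= padlen:
        raise ValidationError(
            f"series of length {len(x)} too short to filter (need > {padlen})"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=sample_rate_hz)
    return filtfilt(b, a, x, padtype="even", padlen=padlen)


def magnitude_normalize(signal: np.ndarray) -> np.ndarray:
    """Scale a series by its peak absolute value into [-1, 1].

    All-zero input passes through unchanged (no division by zero).
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot normalize an empty series")
    peak = np.max(np.abs(x))
    if peak == 0:
        return x.copy()
    return x / peak


def apply_time_offset(trial: IMUTrial, offset_s: float) -> IMUTrial:
    """Shift a trial's clock by ``offset_s`` (video-to-IMU alignment)."""
    if not np.isfinite(offset_s):
        raise ValidationError("offset must be finite")
    return dataclasses.replace(trial, sample_times=trial.sample_times + offset_s)


@dataclass
class PreprocessedTrial:
    """An IMUTrial after conditioning, plus the continuous azimuth."""

    trial: IMUTrial
    corrected_azimuth: np.ndarray
    channels: dict  # conditioned signal per channel name
    filtered: bool = True
    normalized: bool = True

    @property
    def trial_id(self) -> str:
        return self.trial.trial_id

    @property
    def participant_id(self) -> str:
        return self.trial.participant_id

    @property
    def sample_times(self) -> np.ndarray:
        return self.trial.sample_times

    @property
    def n_samples(self) -> int:
        return self.trial.n_samples

    def signal(self, name: str) -> np.ndarray:
        """Conditioned signal for ``name``; 'azimuth' yields the continuous series."""
        return self.channels[name]


def preprocess_trial(trial: IMUTrial, config: PipelineConfig | None = None) -> PreprocessedTrial:
    """Condition a trial: azimuth correction, filtering, normalization.

    Order of operations: correct azimuth first, then low-pass filter the
    acceleration and angular-velocity channels, then magnitude-normalize
    those same channels per trial.  Pitch and roll pass through untouched.
    """
    cfg = config or PipelineConfig()
    corrected = correct_azimuth(
        trial.azimuth,
        threshold_deg=cfg.azimuth_jump_threshold_deg,
        mode=cfg.azimuth_correction_mode,
    )
    channels: dict[str, np.ndarray] = {}
    for name in SIGNAL_COLUMNS:
        if name == "azimuth":
            channels[name] = corrected
        elif name in FILTERED_CHANNELS:
            filtered = lowpass_zero_lag(
                trial.channel(name),
                order=cfg.filter_order,
                cutoff_hz=cfg.filter_cutoff_hz,
                sample_rate_hz=cfg.sample_rate_hz,
            )
            channels[name] = magnitude_normalize(filtered)
        else:
            channels[name] = trial.channel(name).copy()
    return PreprocessedTrial(trial=trial, corrected_azimuth=corrected, channels=channels)
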