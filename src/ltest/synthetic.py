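"""Synthetic L test trial generator with exact ground truth.

No public dataset of waist-worn smartphone IMU recordings of the L test
exists, so the pipeline is exercised on simulated trials whose ground truth
is known by construction.  A trial is a sequence of eleven phases: sitting
idle, stand-up, then alternating straight walks and the four turns
(90, 180, 90, 180 degrees; the third turn is signed opposite so the default
circuit nets +360 degrees of heading), and finally sit-down.

Signal model (structure over physiological realism):

* heading climbs by the signed turn magnitude during each turn along a
  smoothed-trapezoid ramp whose rate pulses at the step frequency (people
  turn in discrete pivot steps) and is flat between turns; the emitted
  azimuth is the heading wrapped into [0, 360), which exercises the
  wrap-correction stage;
* locomotion (from the first walk up to sit-down, turns included — L test
  walking is continuous) places sinusoids at the gait cadence on the
  acceleration and angular-velocity channels and a small yaw/pitch/roll
  sway on the orientation channels (real trunks oscillate in heading while
  walking); foot strikes are recorded at the vertical-acceleration peaks,
  so the mean step time equals 1/cadence;
* stand-up is a single smooth pitch flexion-extension hump with a vertical
  acceleration pulse; sit-down is its sign-opposite;
* the vertical gyro carries the analytic time-derivative of heading, so
  turn rate and heading are mutually consistent;
* independent Gaussian noise is added per channel.

Ground-truth transition times equal the cumulative phase boundaries
exactly, and every generated trial keeps each subtask inside its default
percent data range, so extraction never errors on defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io_model import GroundTruth, IMUTrial, ManifestEntry, SUBTASKS

#: Phase order of one trial.  The six labeled subtasks interleave with
#: unlabeled sitting and walking phases.
PHASES: tuple[str, ...] = (
    "sit_idle",
    "stand_up",
    "walk1",
    "turn90_1",
    "walk2",
    "turn180_1",
    "walk3",
    "turn90_2",
    "walk4",
    "turn180_2",
    "sit_down",
)

WALK_PHASES = ("walk1", "walk2", "walk3", "walk4")
TURN_PHASES = ("turn90_1", "turn180_1", "turn90_2", "turn180_2")


def _default_durations() -> dict[str, float]:
    # Able-bodied base: ~30.5 s total at a brisk self-selected pace.
    return {
        "sit_idle": 2.0,
        "stand_up": 2.0,
        "walk1": 3.5,
        "turn90_1": 2.0,
        "walk2": 3.5,
        "turn180_1": 3.0,
        "walk3": 3.5,
        "turn90_2": 2.0,
        "walk4": 3.5,
        "turn180_2": 3.0,
        "sit_down": 2.5,
    }


def _default_turn_angles() -> dict[str, float]:
    # Signed turn magnitudes; the circuit nets +360 degrees.
    return {
        "turn90_1": 90.0,
        "turn180_1": 180.0,
        "turn90_2": -90.0,
        "turn180_2": 180.0,
    }


def _default_gait_amplitude() -> dict[str, float]:
    # Peak amplitudes of the gait oscillation during locomotion.  The
    # acceleration amplitudes are trunk-level values; pitch/roll/azimuth are
    # angular sway amplitudes (half the segment's rotation range during a
    # stride; pelvic transverse-plane rotation is the largest).  Gyroscope
    # channels are not parameterized: they are the analytic derivatives of
    # the orientation channels, keeping rate and angle mutually consistent.
    return {
        "lin_acc_ml": 0.8,  # m/s^2
        "lin_acc_v": 1.5,
        "lin_acc_ap": 1.0,
        "pitch": 2.0,  # deg
        "roll": 2.0,
        "azimuth": 4.0,  # pelvic rotation sway about the mean heading
    }


def _default_noise_sigma() -> dict[str, float]:
    # Additive white sensor noise per channel (same units as the channel).
    return {
        "lin_acc_ml": 0.05,
        "lin_acc_v": 0.05,
        "lin_acc_ap": 0.05,
        "gyro_ml": 1.0,
        "gyro_v": 1.0,
        "gyro_ap": 1.0,
        "pitch": 0.3,
        "roll": 0.3,
        "azimuth": 0.5,
    }


@dataclass
class SyntheticTrialSpec:
    """Complete description of one simulated trial."""

    participant_id: str = "P00"
    trial_id: str = "P00_T1"
    cohort: str = "able_bodied"
    durations: dict[str, float] = field(default_factory=_default_durations)
    turn_angles: dict[str, float] = field(default_factory=_default_turn_angles)
    cadence_hz: float = 1.8  # steps per second
    gait_amplitude: dict[str, float] = field(default_factory=_default_gait_amplitude)
    pitch_excursion_deg: float = 30.0  # stand-up / sit-down trunk hump
    vertical_pulse: float = 2.0  # m/s^2 pulse during stand-up / sit-down
    stride_variability: float = 0.15  # sd of the per-step amplitude gain
    turn_step_modulation: float = 0.15  # per-step share of turn angle that oscillates
    impact_gyro_deg_s: float = 35.0  # peak of the heel-strike rate transient
    impact_width_s: float = 0.12  # duration of that transient
    noise_sigma: dict[str, float] = field(default_factory=_default_noise_sigma)
    initial_heading_deg: float = 0.0
    sample_rate_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.durations) != set(PHASES):
            raise ValidationError("durations must cover exactly the trial phases")
        if any(d <= 0 for d in self.durations.values()):
            raise ValidationError("all phase durations must be positive")
        if set(self.turn_angles) != set(TURN_PHASES):
            raise ValidationError("turn_angles must cover exactly the four turns")
        if self.cadence_hz <= 0:
            raise ValidationError("cadence must be positive")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise ValidationError("noise sigma must be non-negative")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample rate must be positive")

    @property
    def total_duration(self) -> float:
        return sum(self.durations.values())

    def phase_bounds(self) -> dict[str, tuple[float, float]]:
        """Start/end time of every phase (cumulative durations)."""
        bounds = {}
        t = 0.0
        for phase in PHASES:
            bounds[phase] = (t, t + self.durations[phase])
            t += self.durations[phase]
        return bounds

    def scaled(self, time_scale: float = 1.0, noise_scale: float = 1.0) -> "SyntheticTrialSpec":
        """A copy with all durations and/or noise sigmas scaled.

        Uniform time scaling preserves every subtask's position as a
        fraction of trial length, so the default percent ranges still
        cover the ground truth; it exists so tests can shrink runtime.
        """
        return dataclasses.replace(
            self,
            durations={k: v * time_scale for k, v in self.durations.items()},
            noise_sigma={k: v * noise_scale for k, v in self.noise_sigma.items()},
        )


_TURN_BLEND = 0.2  # fraction of the turn spent easing in / easing out


def _turn_profile(u: np.ndarray, e: float = _TURN_BLEND) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed-trapezoid ramp 0 -> 1 and its derivative in u.

    Constant rotation rate with quadratic ease-in/ease-out blends of width
    ``e``: turn onset and completion are brisk (annotators can mark them)
    but C1-continuous.
    """
    u = np.clip(u, 0.0, 1.0)
    norm = 1.0 / (1.0 - e)
    b = np.where(
        u < e,
        u**2 / (2.0 * e) * norm,
        np.where(
            u > 1.0 - e,
            1.0 - (1.0 - u) ** 2 / (2.0 * e) * norm,
            (u - e / 2.0) * norm,
        ),
    )
    bdot = np.where(
        u < e,
        u / e * norm,
        np.where(u > 1.0 - e, (1.0 - u) / e * norm, norm),
    )
    return b, bdot


def generate_trial(spec: SyntheticTrialSpec) -> tuple[IMUTrial, GroundTruth]:
    """Simulate one trial and its exact ground truth. Deterministic in seed."""
    fs = spec.sample_rate_hz
    # final sample at or past the nominal duration so the recording covers
    # the annotated sit-down end
    n = int(np.ceil(spec.total_duration * fs)) + 1
    t = np.arange(n) / fs
    bounds = spec.phase_bounds()
    rng = np.random.default_rng(spec.seed)

    heading = np.full(n, spec.initial_heading_deg, dtype=float)
    turn_rate = np.zeros(n)
    # Inside a turn the pelvic yaw oscillation IS the pivot-step rotation
    # pattern (modeled below as the turn's rate modulation), so the
    # straight-walking yaw sway fades out there rather than double-count
    # the same degree of freedom.
    yaw_env = np.ones(n)
    yaw_env_dot = np.zeros(n)
    for phase in TURN_PHASES:
        t0, t1 = bounds[phase]
        angle = spec.turn_angles[phase]
        dur = t1 - t0
        after = t >= t1
        during = (t >= t0) & ~after
        u = (t[during] - t0) / dur
        # Turning proceeds in discrete pivot steps: the yaw rate pulses at
        # roughly the step frequency (dipping between steps, never
        # reversing) while the integrated heading climbs steadily.
        k_steps = max(1, int(round(dur * spec.cadence_hz)))
        # Motor execution varies turn to turn: the sharpness of the rate
        # profile and the depth and phasing of the per-step rotation pulses
        # are random, so the trial's peak yaw rate (and with it the
        # per-trial normalization constant) jitters.
        blend = float(rng.uniform(0.15, 0.45))
        gain = float(np.clip(rng.normal(1.0, 0.4), 0.2, 1.8))
        phi = float(rng.uniform(0.0, 2.0 * np.pi))
        base, base_rate = _turn_profile(u, e=blend)
        a_step = gain * spec.turn_step_modulation * angle / k_steps
        two_pi_k = 2.0 * np.pi * k_steps
        mod = a_step * np.sin(two_pi_k * u + phi) * np.sin(np.pi * u)
        mod_rate = a_step * (
            two_pi_k * np.cos(two_pi_k * u + phi) * np.sin(np.pi * u)
            + np.pi * np.cos(np.pi * u) * np.sin(two_pi_k * u + phi)
        )
        heading[during] += angle * base + mod
        heading[after] += angle
        turn_rate[during] += (angle * base_rate + mod_rate) / dur
        yaw_env[during] = 1.0 - np.sin(np.pi * u)
        yaw_env_dot[during] = -(np.pi / dur) * np.cos(np.pi * u)

    # Locomotion spans walk1 through the last turn: participants keep
    # stepping through turns, so gait oscillation (and foot strikes) are
    # continuous from the first walk to the start of sit-down.
    loc0 = bounds["walk1"][0]
    loc1 = bounds["sit_down"][0]
    locomotion = (t >= loc0) & (t < loc1)
    # Vertical/AP acceleration and pitch oscillate once per step; pelvic
    # yaw (azimuth), roll and ML acceleration once per stride (two steps).
    step_phase = 2.0 * np.pi * spec.cadence_hz * (t - loc0)
    stride_phase = step_phase / 2.0
    gait = np.where(locomotion, np.sin(step_phase), 0.0)
    gait_q = np.where(locomotion, np.cos(step_phase), 0.0)
    sway = np.where(locomotion, np.sin(stride_phase), 0.0)
    sway_q = np.where(locomotion, np.cos(stride_phase), 0.0)
    # foot strikes at the vertical-acceleration peaks (phase = pi/2 + 2*pi*k)
    foot_strikes = []
    k = 0
    while True:
        strike = loc0 + (0.25 + k) / spec.cadence_hz
        if strike >= loc1:
            break
        foot_strikes.append(strike)
        k += 1

    # Stride-to-stride motor variability: a smooth per-step amplitude gain
    # (gait is never perfectly periodic; amputee gait especially so).  The
    # same envelope scales accelerations, angular sway, and the sway-rate
    # terms of the gyroscopes (its own slow derivative is neglected).
    if spec.stride_variability > 0 and len(foot_strikes) >= 2:
        gains = np.clip(
            rng.normal(1.0, spec.stride_variability, size=len(foot_strikes)),
            0.5,
            1.5,
        )
        envelope = np.interp(t, np.asarray(foot_strikes), gains)
    else:
        envelope = np.ones(n)
    gait *= envelope
    gait_q *= envelope
    sway *= envelope
    sway_q *= envelope

    amp = spec.gait_amplitude

    def hump(phase: str) -> tuple[np.ndarray, np.ndarray]:
        """sin(pi*u) bump over a phase and its mask."""
        t0, t1 = bounds[phase]
        mask = (t >= t0) & (t < t1)
        u = (t[mask] - t0) / (t1 - t0)
        return np.sin(np.pi * u), mask

    stand_bump, stand_mask = hump("stand_up")
    sit_bump, sit_mask = hump("sit_down")

    # Angular rates of the gait sway: d/dt of (amp * sin/cos phase).
    omega_step = 2.0 * np.pi * spec.cadence_hz
    omega_stride = np.pi * spec.cadence_hz  # stride cycle is two steps

    pitch = amp["pitch"] * gait_q
    pitch[stand_mask] += spec.pitch_excursion_deg * stand_bump
    pitch[sit_mask] -= spec.pitch_excursion_deg * sit_bump

    lin_acc_v = amp["lin_acc_v"] * gait
    lin_acc_v[stand_mask] += spec.vertical_pulse * stand_bump
    lin_acc_v[sit_mask] -= spec.vertical_pulse * sit_bump

    # Gyroscopes are the analytic time-derivatives of the orientation
    # channels: ML gyro <- pitch (sway + stand/sit hump), vertical gyro <-
    # heading (turn ramp + yaw sway), AP gyro <- roll sway.
    gyro_ml = -amp["pitch"] * omega_step * gait  # d/dt of amp*cos(step phase)
    for sign, (bump_mask, phase) in (
        (1.0, (stand_mask, "stand_up")),
        (-1.0, (sit_mask, "sit_down")),
    ):
        t0, t1 = bounds[phase]
        u = (t[bump_mask] - t0) / (t1 - t0)
        gyro_ml[bump_mask] += (
            sign * spec.pitch_excursion_deg * np.pi * np.cos(np.pi * u) / (t1 - t0)
        )
    # d/dt of amp * yaw_env * sway (the envelope's own rate included)
    gyro_v = turn_rate + amp["azimuth"] * (
        yaw_env * omega_stride * sway_q + yaw_env_dot * sway
    )
    gyro_ap = amp["roll"] * omega_stride * sway_q

    # Heel-strike impact transients: each step injects a short (~0.12 s)
    # angular-rate spike at the pelvis, alternating in sign with the
    # striking foot and varying in amplitude.  They ride on every gyro
    # channel and are the dominant non-turn content of raw yaw rate —
    # integrated heading barely sees them.
    if spec.impact_gyro_deg_s > 0 and foot_strikes:
        w = spec.impact_width_s
        impact_targets = (gyro_ml, gyro_v, gyro_ap)
        amps = spec.impact_gyro_deg_s * np.clip(
            rng.normal(1.0, 0.3, size=(len(foot_strikes), len(impact_targets))),
            0.2,
            2.0,
        )
        for k, strike in enumerate(foot_strikes):
            mask = np.abs(t - strike) <= w / 2.0
            if not mask.any():
                continue
            pulse = np.cos(np.pi * (t[mask] - strike) / w) ** 2
            sign = 1.0 if k % 2 == 0 else -1.0
            for c, target in enumerate(impact_targets):
                target[mask] += sign * amps[k, c] * pulse

    channels = {
        "lin_acc_ml": amp["lin_acc_ml"] * sway_q,
        "lin_acc_v": lin_acc_v,
        "lin_acc_ap": amp["lin_acc_ap"] * gait,
        "gyro_ml": gyro_ml,
        "gyro_v": gyro_v,
        "gyro_ap": gyro_ap,
        "pitch": pitch,
        "roll": amp["roll"] * sway,
        "azimuth": heading + amp["azimuth"] * yaw_env * sway,
    }
    for name in channels:
        sigma = spec.noise_sigma[name]
        if sigma > 0:
            channels[name] = channels[name] + rng.normal(0.0, sigma, size=n)
    az = np.mod(channels["azimuth"], 360.0)
    az[az >= 360.0] = 0.0  # np.mod of a tiny negative returns exactly 360.0
    channels["azimuth"] = az

    trial = IMUTrial(
        trial_id=spec.trial_id,
        participant_id=spec.participant_id,
        cohort=spec.cohort,
        sample_times=t,
        sample_rate_hz=fs,
        **channels,
    )
    events = {s: bounds[s] for s in SUBTASKS}
    gt = GroundTruth(
        trial_id=spec.trial_id,
        subtask_events=events,
        foot_strikes=np.asarray(foot_strikes),
        total_time=spec.total_duration,
    )
    return trial, gt


def _jittered_spec(
    base: SyntheticTrialSpec,
    participant_id: str,
    trial_id: str,
    cohort: str,
    variability: float,
    rng: np.random.Generator,
    seed: int,
) -> SyntheticTrialSpec:
    """Per-trial copy of ``base`` with multiplicative duration/cadence jitter."""
    factors = {
        phase: 1.0 + variability * rng.uniform(-1.0, 1.0) for phase in PHASES
    }
    cadence = base.cadence_hz * (1.0 + variability * rng.uniform(-1.0, 1.0))
    movement_scale = 1.25 if cohort == "amputee" else 1.0
    cadence_scale = 0.8 if cohort == "amputee" else 1.0
    durations = {
        phase: base.durations[phase]
        * factors[phase]
        * (movement_scale if phase != "sit_idle" else 1.0)
        for phase in PHASES
    }
    return dataclasses.replace(
        base,
        participant_id=participant_id,
        trial_id=trial_id,
        cohort=cohort,
        durations=durations,
        cadence_hz=cadence * cadence_scale,
        seed=seed,
    )


def generate_cohort(
    n_amputee: int,
    n_able: int,
    base_spec: SyntheticTrialSpec | None = None,
    variability: float = 0.08,
    seed: int = 0,
) -> list[ManifestEntry]:
    """Simulate a study cohort: 5 trials per able-bodied participant, 1 per amputee.

    Amputee specs are slower by default (all movement durations x1.25,
    cadence x0.8); a per-participant multiplicative jitter of +-``variability``
    is applied to every phase duration and the cadence.  Deterministic in
    ``seed``.
    """
    if n_amputee < 2:
        raise ValidationError("need at least two amputee participants")
    base = base_spec or SyntheticTrialSpec()
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []
    for i in range(n_able):
        pid = f"AB{i:02d}"
        for j in range(5):
            spec = _jittered_spec(
                base,
                pid,
                f"{pid}_T{j + 1}",
                "able_bodied",
                variability,
                rng,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trial, gt = generate_trial(spec)
            entries.append(ManifestEntry(trial, gt, pid, "able_bodied"))
    for i in range(n_amputee):
        pid = f"LLA{i:02d}"
        spec = _jittered_spec(
            base,
            pid,
            f"{pid}_T1",
            "amputee",
            variability,
            rng,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        trial, gt = generate_trial(spec)
        entries.append(ManifestEntry(trial, gt, pid, "amputee"))
    return entries
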