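"""Forward co-simulation of ground-truth lower-limb kinematics and the raw
MARG streams a body-worn sensor suite would record, plus 100 Hz reference
joint-angle traces emulating an optical motion-capture system.

The rig is deliberately minimal but physically self-consistent:

* Squat-like movements drive hip/knee/ankle flexion with raised-cosine
  repetition cycles; segment orientations are composed down the chain
  pelvis → thigh → shank → foot, and sensor positions follow a
  fixed-length-segment chain so that thigh/shank sensors see genuine
  linear acceleration.
* Gait-like movements (shuffle-walk, bear crawl) move the foot through
  minimum-jerk swing arcs separated by zero-velocity stance dwells, with
  joint excursions confined to swing; initial/final contact and stance
  windows are therefore known exactly.
* Sensors are mounted at arbitrary (seeded) fixed orientation offsets on
  their segments — an identity mount would mask alignment-transform bugs.

Each sensor stream is synthesized from the same orientation/position
truth it will later be asked to recover: gyro = body angular rate (+ bias
random walk + white noise), accel = sensor-frame specific force
(+ white noise), mag = sensor-frame Earth field with optional hard/soft
iron distortion (+ white noise), decimated to a tenth of the IMU rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align as _align
from .preprocess import GRAVITY, IMU_RATE_HZ, MargRecording, PipelineConfig
from .quatcore import (
    canonicalize,
    conjugate,
    hamilton,
    normalize,
    quat_from_axis_angle,
    quat_to_dcm,
    rotate_vector,
)

__all__ = [
    "MotionProfile",
    "GroundTruth",
    "SensorErrorModel",
    "make_motion_profile",
    "generate_ground_truth",
    "synthesize_marg",
    "synthesize_reference",
    "random_mounts",
    "EARTH_FIELD",
]

# Magnetic field in the global frame: 50 µT magnitude, 60° downward
# inclination (southern-hemisphere-like dip), x = magnetic north.
EARTH_FIELD = np.array([25.0, 0.0, -25.0 * np.sqrt(3.0)])

SEGMENTS = _align.SEGMENTS
_JOINT_CHAIN = [("hip", "pelvis", "thigh"), ("knee", "thigh", "shank"), ("ankle", "shank", "foot")]

# Segment lengths (m) and sensor offsets from the distal joint of each
# segment, matching the placement scheme: thigh sensor ~150 mm proximal of
# the knee, shank sensor ~100 mm distal of the knee, foot sensor near the
# ankle, pelvis sensor on the sacrum.
_SHANK_LEN = 0.40
_THIGH_LEN = 0.40


@dataclass
class MotionProfile:
    """Movement description: joint excursions plus gait parameters."""

    movement: str
    amplitudes_deg: dict  # joint -> peak flexion excursion per repetition
    repetitions: int = 5
    cycle_s: float = 2.5  # duration of one squat-like repetition
    stride_length_m: float = 0.0
    stride_time_s: float = 0.0
    stance_time_s: float = 0.0
    n_strides: int = 0
    lead_in_s: float = 1.0  # static calibration-pose span before movement
    lead_out_s: float = 0.5
    fs: float = IMU_RATE_HZ
    heading_deg: float = 0.0  # direction of travel / facing in the global frame

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes_deg.values()):
            raise ValueError("joint amplitudes must be non-negative")
        if self.n_strides and not self.stance_time_s < self.stride_time_s:
            raise ValueError("stance time must be shorter than stride time")

    @property
    def is_gait(self) -> bool:
        return self.n_strides > 0

    @property
    def duration_s(self) -> float:
        if self.is_gait:
            move = self.n_strides * self.stride_time_s + self.stance_time_s
        else:
            move = self.repetitions * self.cycle_s
        return self.lead_in_s + move + self.lead_out_s


_PROFILES = {
    # Squat-family defaults: mean hip/knee/ankle excursions of the reference
    # system for each movement; five repetitions per set.
    "squat": dict(amplitudes_deg={"hip": 96.8, "knee": 121.2, "ankle": 31.2}, repetitions=5, cycle_s=2.5),
    "box_squat": dict(amplitudes_deg={"hip": 85.5, "knee": 91.6, "ankle": 21.1}, repetitions=5, cycle_s=2.5),
    "sandbag_pickup": dict(amplitudes_deg={"hip": 97.1, "knee": 126.8, "ankle": 38.9}, repetitions=3, cycle_s=3.0),
    # Gait-family defaults at the reported operating points (stride length /
    # stride time / stance time), with modest swing-phase joint excursions.
    "shuffle_walk": dict(
        amplitudes_deg={"hip": 12.1, "knee": 29.1, "ankle": 10.0},
        stride_length_m=0.339,
        stride_time_s=0.846,
        stance_time_s=0.568,
        n_strides=6,
    ),
    "bear_crawl": dict(
        amplitudes_deg={"hip": 33.3, "knee": 40.0, "ankle": 10.0},
        stride_length_m=0.515,
        stride_time_s=1.912,
        stance_time_s=1.502,
        n_strides=3,
    ),
}


def make_motion_profile(tag: str, **overrides) -> MotionProfile:
    """Named movement profile with study-condition defaults; overridable."""
    if tag not in _PROFILES:
        raise KeyError(f"unknown movement {tag!r}; expected one of {sorted(_PROFILES)}")
    params = dict(_PROFILES[tag])
    amps = dict(params.pop("amplitudes_deg"))
    amps.update(overrides.pop("amplitudes_deg", {}))
    params.update(overrides)
    return MotionProfile(movement=tag, amplitudes_deg=amps, **params)


@dataclass
class GroundTruth:
    """Everything downstream stages are later asked to recover."""

    time: np.ndarray  # (n,) s at the IMU rate
    seg_quat: dict  # segment -> (n, 4) segment-to-global quaternions
    joint_flexion_deg: dict  # joint -> (n,) degrees
    sensor_pos: dict  # segment -> (n, 3) m, sensor position in the global frame
    rep_windows: list  # [(start, peak, end)] sample indices per repetition
    ic_times: np.ndarray  # (k,) s initial contacts
    fc_times: np.ndarray  # (k,) s final contacts
    stance_windows: list  # [(start_idx, end_idx)] per stance
    stride_length_m: np.ndarray  # (k-1,) per-stride truth
    stride_time_s: np.ndarray
    stance_time_s: np.ndarray
    profile: MotionProfile = None

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


def _minjerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk 0→1 profile: zero velocity and acceleration at both ends."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _squat_flexion(profile: MotionProfile, t: np.ndarray) -> dict:
    """Raised-cosine repetition cycles, zero in lead-in/lead-out."""
    tm = t - profile.lead_in_s
    phase = np.zeros_like(t)
    active = (tm >= 0) & (tm < profile.repetitions * profile.cycle_s)
    phase[active] = 0.5 * (1.0 - np.cos(2 * np.pi * tm[active] / profile.cycle_s))
    return {j: a * phase for j, a in profile.amplitudes_deg.items()}


def _gait_flexion_and_foot(profile: MotionProfile, t: np.ndarray):
    """Swing-confined joint cycles plus a min-jerk foot trajectory."""
    n = t.size
    swing_s = profile.stride_time_s - profile.stance_time_s
    pos_fwd = np.zeros(n)
    phase = np.zeros(n)  # 0..1 bump during each swing
    ic, fc, stances = [], [], []
    t0 = profile.lead_in_s
    fs = profile.fs
    # Stance i starts at t0 + i*T_stride; the first stance really begins at
    # the start of the recording (the lead-in is itself a stance) and the
    # last one extends to the end, so only interior contacts are true events.
    for i in range(profile.n_strides + 1):
        stance_start = t0 + i * profile.stride_time_s
        stance_end = stance_start + profile.stance_time_s
        if i > 0:
            ic.append(stance_start)
        if i < profile.n_strides:
            fc.append(stance_end)
        # Window indices rounded inward so the foot is exactly still on
        # every sample the truth labels as stance.
        s_idx = 0 if i == 0 else int(np.ceil(stance_start * fs))
        e_idx = n - 1 if i == profile.n_strides else int(np.floor(stance_end * fs))
        stances.append((s_idx, min(e_idx, n - 1)))
        if i < profile.n_strides:
            tau = (t - stance_end) / swing_s
            in_swing = (tau >= 0) & (tau <= 1)
            pos_fwd += profile.stride_length_m * np.where(tau > 1, 1.0, np.where(in_swing, _minjerk(tau), 0.0))
            phase[in_swing] += 0.5 * (1.0 - np.cos(2 * np.pi * tau[in_swing]))
    flex = {j: a * phase for j, a in profile.amplitudes_deg.items()}
    heading = np.deg2rad(profile.heading_deg)
    direction = np.array([np.cos(heading), np.sin(heading), 0.0])
    foot_pos = pos_fwd[:, None] * direction
    return flex, foot_pos, np.array(ic), np.array(fc), stances


def generate_ground_truth(profile: MotionProfile) -> GroundTruth:
    """Build the kinematic truth for a movement profile."""
    n = int(round(profile.duration_s * profile.fs)) + 1
    t = np.arange(n) / profile.fs

    if profile.is_gait:
        flex, foot_pos, ic, fc, stances = _gait_flexion_and_foot(profile, t)
    else:
        flex = _squat_flexion(profile, t)
        foot_pos = np.zeros((n, 3))
        ic = np.array([])
        fc = np.array([])
        stances = []

    heading_q = quat_from_axis_angle([0, 0, 1], np.deg2rad(profile.heading_deg))
    seg_quat = {"pelvis": np.tile(heading_q, (n, 1))}
    for joint, prox, dist in _JOINT_CHAIN:
        sign = _align.FLEXION_SIGN[joint]
        qj = quat_from_axis_angle([0, 1, 0], sign * np.deg2rad(flex[joint]))
        seg_quat[dist] = hamilton(seg_quat[prox], qj)

    # Sensor positions: squat-family movements pivot about the (planted)
    # ankle, so build the chain ankle -> knee -> hip and place each sensor at
    # its documented offset; gait movements translate the foot and pelvis.
    sensor_pos = {}
    if profile.is_gait:
        speed_ramp = np.clip((t - profile.lead_in_s) / profile.stride_time_s, 0.0, None)
        total = profile.n_strides * profile.stride_time_s
        ramp = _minjerk(speed_ramp / profile.n_strides)  # smooth 0->1 over the walk
        heading = np.deg2rad(profile.heading_deg)
        direction = np.array([np.cos(heading), np.sin(heading), 0.0])
        pelvis_fwd = profile.n_strides * profile.stride_length_m * ramp
        sensor_pos["pelvis"] = pelvis_fwd[:, None] * direction + np.array([0, 0, 1.0])
        sensor_pos["foot"] = foot_pos
        sensor_pos["thigh"] = np.tile(np.array([0.0, 0.0, 0.6]), (n, 1))
        sensor_pos["shank"] = np.tile(np.array([0.0, 0.0, 0.3]), (n, 1))
    else:
        ankle = np.zeros((n, 3))
        up_shank = rotate_vector(seg_quat["shank"], np.array([0.0, 0.0, 1.0]))
        up_thigh = rotate_vector(seg_quat["thigh"], np.array([0.0, 0.0, 1.0]))
        knee = ankle + _SHANK_LEN * up_shank
        hip = knee + _THIGH_LEN * up_thigh
        sensor_pos["foot"] = ankle + rotate_vector(seg_quat["foot"], np.array([0.05, 0.0, 0.05]))
        sensor_pos["shank"] = ankle + 0.30 * up_shank  # ~100 mm distal of the knee
        sensor_pos["thigh"] = knee + 0.25 * up_thigh  # ~150 mm proximal of the knee
        sensor_pos["pelvis"] = hip + rotate_vector(seg_quat["pelvis"], np.array([-0.08, 0.0, 0.05]))

    # Repetition windows from the analytic cycle boundaries.
    rep_windows = []
    if not profile.is_gait:
        fs = profile.fs
        for r in range(profile.repetitions):
            s = int(round((profile.lead_in_s + r * profile.cycle_s) * fs))
            p = int(round((profile.lead_in_s + (r + 0.5) * profile.cycle_s) * fs))
            e = int(round((profile.lead_in_s + (r + 1) * profile.cycle_s) * fs))
            rep_windows.append((s, p, min(e, n - 1)))

    # Per-stride truth: one stride length per swing (n_strides of them);
    # stride/stance times as measurable from interior IC/FC events.
    ns = profile.n_strides
    stride_len = np.full(ns, profile.stride_length_m) if ns else np.array([])
    stride_t = np.full(max(ns - 1, 0), profile.stride_time_s)
    stance_t = np.full(max(ns - 1, 0), profile.stance_time_s)

    return GroundTruth(
        time=t,
        seg_quat={s: canonicalize(q) for s, q in seg_quat.items()},
        joint_flexion_deg=flex,
        sensor_pos=sensor_pos,
        rep_windows=rep_windows,
        ic_times=ic,
        fc_times=fc,
        stance_windows=stances,
        stride_length_m=stride_len,
        stride_time_s=stride_t,
        stance_time_s=stance_t,
        profile=profile,
    )


@dataclass
class SensorErrorModel:
    """Generative sensor-error parameters (variances, distortions, seed)."""

    accel_noise_var: float = 0.0  # (m/s^2)^2 white
    gyro_noise_var: float = 0.0  # (rad/s)^2 white
    gyro_drift_var: float = 0.0  # (rad/s)^2 per-sample bias random walk
    mag_noise_var: float = 0.0  # µT^2 white
    hard_iron: np.ndarray = field(default_factory=lambda: np.zeros(3))
    soft_iron: np.ndarray = field(default_factory=lambda: np.eye(3))
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m/s^2, constant
    gravity: float = GRAVITY
    earth_field: np.ndarray = field(default_factory=lambda: EARTH_FIELD.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accel_noise_var", "gyro_noise_var", "gyro_drift_var", "mag_noise_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_config(cls, config: PipelineConfig, seed: int = 0, **kw) -> "SensorErrorModel":
        """Noise magnitudes taken from a processing configuration's tuning set."""
        return cls(
            accel_noise_var=config.accel_noise_var,
            gyro_noise_var=config.gyro_noise_var,
            gyro_drift_var=config.gyro_drift_var,
            mag_noise_var=config.mag_disturbance_var,
            seed=seed,
            **kw,
        )


def random_mounts(seed: int = 0, max_angle_deg: float = 180.0) -> dict:
    """Seeded arbitrary fixed sensor-mount quaternions, one per segment."""
    rng = np.random.default_rng(seed)
    mounts = {}
    for seg in SEGMENTS:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
        if seg == "foot":
            # The foot sensor is the one deliberately placed device: its
            # x-axis must stay anterior/posterior, so only allow roll about x.
            mounts[seg] = quat_from_axis_angle([1, 0, 0], np.deg2rad(rng.uniform(-30, 30)))
        else:
            mounts[seg] = canonicalize(quat_from_axis_angle(axis, ang))
    return mounts


def _body_rates(q: np.ndarray, dt: float) -> np.ndarray:
    """Sensor-frame angular velocity by central differences of orientation."""
    n = q.shape[0]
    omega = np.zeros((n, 3))
    dq = hamilton(conjugate(q[:-2]), q[2:])  # body-frame increment over 2*dt
    dq = canonicalize(dq)
    w = np.clip(dq[:, 0], -1.0, 1.0)
    ang = 2.0 * np.arccos(w)
    s = np.sqrt(np.maximum(1.0 - w * w, 0.0))
    scale = np.where(s > 1e-12, ang / np.maximum(s, 1e-300), 2.0)
    omega[1:-1] = dq[:, 1:] * scale[:, None] / (2.0 * dt)
    omega[0] = omega[1]
    omega[-1] = omega[-2]
    return omega


def synthesize_marg(
    truth: GroundTruth,
    err: SensorErrorModel | None = None,
    mounts: dict | None = None,
    segments: tuple = SEGMENTS,
) -> dict:
    """Raw MARG recordings (one per requested segment) consistent with the truth.

    Bit-reproducible for a fixed :class:`SensorErrorModel` seed and segment
    selection.
    """
    err = err or SensorErrorModel()
    mounts = mounts or {seg: np.array([1.0, 0.0, 0.0, 0.0]) for seg in SEGMENTS}
    rng = np.random.default_rng(err.seed)
    t = truth.time
    dt = float(t[1] - t[0])
    n = t.size
    g_vec = np.array([0.0, 0.0, err.gravity])

    out = {}
    for seg in segments:
        q_sensor = canonicalize(hamilton(truth.seg_quat[seg], mounts[seg]))
        R = quat_to_dcm(q_sensor)  # columns: sensor axes in global frame

        gyro = _body_rates(q_sensor, dt)
        if err.gyro_drift_var > 0:
            gyro = gyro + np.cumsum(rng.normal(0.0, np.sqrt(err.gyro_drift_var), (n, 3)), axis=0)
        if err.gyro_noise_var > 0:
            gyro = gyro + rng.normal(0.0, np.sqrt(err.gyro_noise_var), (n, 3))

        pos = truth.sensor_pos[seg]
        acc_global = np.column_stack([np.gradient(np.gradient(pos[:, i], dt), dt) for i in range(3)])
        spec_force_global = acc_global + g_vec
        accel = np.einsum("nij,nj->ni", np.swapaxes(R, 1, 2), spec_force_global)
        accel = accel + err.accel_bias
        if err.accel_noise_var > 0:
            accel = accel + rng.normal(0.0, np.sqrt(err.accel_noise_var), (n, 3))

        mag_clean = np.einsum("nij,nj->ni", np.swapaxes(R, 1, 2), np.tile(err.earth_field, (n, 1)))
        mag_raw = mag_clean @ err.soft_iron.T + err.hard_iron
        if err.mag_noise_var > 0:
            mag_raw = mag_raw + rng.normal(0.0, np.sqrt(err.mag_noise_var), (n, 3))
        mag_time = t[::10]
        mag = mag_raw[::10]

        out[seg] = MargRecording(
            time=t.copy(), accel=accel, gyro=gyro, mag=mag, mag_time=mag_time, segment=seg
        )
    return out


def synthesize_reference(
    truth: GroundTruth,
    noise_deg: float = 0.0,
    dropout_fraction: float = 0.0,
    seed: int = 0,
    ref_rate_hz: float = 100.0,
):
    """100 Hz reference joint-angle traces (optical-system stand-in).

    Returns a DataFrame with ``time_s`` plus one column per joint; optional
    white angular noise and missing-sample dropout (NaN), seeded.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    t_ref = np.arange(0.0, truth.time[-1] + 1e-9, 1.0 / ref_rate_hz)
    data = {"time_s": t_ref}
    for joint, trace in truth.joint_flexion_deg.items():
        ref = np.interp(t_ref, truth.time, trace)
        if noise_deg > 0:
            ref = ref + rng.normal(0.0, noise_deg, ref.size)
        if dropout_fraction > 0:
            drop = rng.random(ref.size) < dropout_fraction
            ref[drop] = np.nan
        data[f"{joint}_deg"] = ref
    return pd.DataFrame(data)
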