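"""Sensor-to-segment alignment and sagittal joint-angle estimation.

The minimal-modeling calibration assumes an upright pose in which the
anterior/posterior axes of all four instrumented segments (pelvis, thigh,
shank, foot) are aligned.  The foot sensor is the one deliberately placed
device: its x-axis points anterior/posterior, so the shared initial
segment frame is built from the horizontal projection of that axis and
the global vertical, and assigned to every segment.

With ``⊗`` the Hamilton product and ``*`` the conjugate, the per-segment
constant alignment transform and the per-sample segment orientation are

    q_seg_t   = q_seg_0* ⊗ q_sensor_0          (calibration instant)
    q_seg_k   = q_sensor_k ⊗ q_seg_t*          (every sample k)
    q_joint_k = q_prox_k* ⊗ q_dist_k           (proximal vs distal segment)

and the reported flexion/extension angle is the sagittal (first) component
of the intrinsic Y-X-Z Euler decomposition of ``q_joint`` — sagittal-first
so that flexion is exact over the full anatomical range instead of being
clipped at ±90° by a mid-sequence singularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .fusion import OrientationSeries
from .quatcore import (
    canonicalize,
    conjugate,
    dcm_to_quat,
    hamilton,
    quat_to_dcm,
    quat_to_euler,
)

__all__ = [
    "SEGMENTS",
    "JOINTS",
    "FLEXION_SIGN",
    "SegmentFrameAssignment",
    "JointAngleSeries",
    "RepetitionWindow",
    "RomSummary",
    "derive_initial_frames",
    "alignment_transform",
    "segment_orientation",
    "joint_angle",
    "flexion_trace",
    "compute_joint_angles",
    "find_calibration_index",
    "segment_repetitions",
    "compute_rom",
]

SEGMENTS = ("pelvis", "thigh", "shank", "foot")

# (proximal, distal) segment pair per joint.
JOINTS = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"), "ankle": ("shank", "foot")}

# Reported angle = sign * sagittal Euler component: flexion positive at the
# hip, knee flexion positive (the knee's sagittal rotation runs opposite the
# hip's in the chain), dorsiflexion positive at the ankle.
FLEXION_SIGN = {"hip": 1.0, "knee": -1.0, "ankle": 1.0}


@dataclass
class SegmentFrameAssignment:
    """Per-segment calibration quantities: q_seg_0, q_sensor_0, q_seg_t."""

    seg_initial: dict  # segment -> assumed initial segment orientation (global)
    sensor_initial: dict  # segment -> observed initial sensor orientation (global)
    transform: dict  # segment -> constant sensor-to-segment alignment quaternion


@dataclass
class JointAngleSeries:
    joint: str
    time: np.ndarray  # (n,) s
    qj: np.ndarray  # (n, 4) joint quaternion
    flexion_deg: np.ndarray  # (n,) sagittal flexion/extension, degrees


@dataclass
class RepetitionWindow:
    start: int
    peak: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.peak < self.end:
            raise ValueError(f"repetition window must satisfy start < peak < end, got {self}")


@dataclass
class RomSummary:
    joint: str
    rom_deg: np.ndarray  # (n_reps,) max - min flexion per repetition
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.rom_deg = np.asarray(self.rom_deg, dtype=float)
        if self.rom_deg.size == 0:
            raise ValueError("ROM summary needs at least one repetition")
        if np.any(self.rom_deg < 0):
            raise ValueError("ROM cannot be negative")
        self.mean = float(self.rom_deg.mean())
        self.sd = float(self.rom_deg.std(ddof=1)) if self.rom_deg.size > 1 else 0.0


def derive_initial_frames(foot_orientation0: np.ndarray, min_tilt_deg: float = 5.0) -> np.ndarray:
    """Shared initial segment orientation from the foot sensor's x-axis.

    x = horizontal projection of the foot sensor x-axis (normalized),
    z = global vertical, y = z × x.  Rejects a foot x-axis within
    ``min_tilt_deg`` of vertical, where the heading is degenerate.
    """
    R = quat_to_dcm(foot_orientation0)
    x_sensor = R[:, 0]  # foot sensor x-axis in the global frame
    horiz = np.array([x_sensor[0], x_sensor[1], 0.0])
    if np.linalg.norm(horiz) < np.sin(np.deg2rad(min_tilt_deg)):
        raise ValueError(
            "foot sensor x-axis is within "
            f"{min_tilt_deg}° of vertical; anterior/posterior heading is degenerate"
        )
    x = horiz / np.linalg.norm(horiz)
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    return dcm_to_quat(np.column_stack([x, y, z]))


def alignment_transform(qseg_o_GF: np.ndarray, qMARG_o_GF: np.ndarray) -> np.ndarray:
    """Constant sensor-to-segment transform: ``q_seg_0* ⊗ q_sensor_0``."""
    return canonicalize(hamilton(conjugate(qseg_o_GF), qMARG_o_GF))


def segment_orientation(qMARG_k_GF: np.ndarray, qseg_t: np.ndarray) -> np.ndarray:
    """Per-sample segment orientation: ``q_sensor_k ⊗ q_seg_t*``."""
    return hamilton(qMARG_k_GF, conjugate(qseg_t))


def joint_angle(q_prox: np.ndarray, q_dist: np.ndarray) -> np.ndarray:
    """Joint quaternion as the orientation difference ``q_prox* ⊗ q_dist``."""
    return hamilton(conjugate(q_prox), q_dist)


def flexion_trace(qj: np.ndarray, sign: float = 1.0, sequence: str = "YXZ") -> np.ndarray:
    """Sagittal flexion/extension (degrees) from joint quaternions."""
    ang = np.atleast_2d(quat_to_euler(qj, sequence=sequence, degrees=True))
    return sign * ang[..., 0].reshape(np.shape(qj)[:-1])


def find_calibration_index(
    gyro: np.ndarray,
    fs: float,
    rate_thresh: float = 0.1,
    min_duration_s: float = 0.25,
) -> int:
    """First sample of the initial quasi-static window (the calibration pose).

    Scans for the first run of at least ``min_duration_s`` in which the gyro
    magnitude stays below ``rate_thresh`` rad/s; robust to start-of-recording
    transients, unlike taking sample 0 literally.
    """
    mag = np.linalg.norm(np.asarray(gyro, dtype=float), axis=1)
    still = mag < rate_thresh
    need = max(1, int(round(min_duration_s * fs)))
    run = 0
    for i, s in enumerate(still):
        run = run + 1 if s else 0
        if run >= need:
            return i - need + 1
    raise ValueError("no initial quasi-static window found; cannot establish the calibration pose")


def build_assignment(
    orientations: dict,
    cal_index: int = 0,
) -> SegmentFrameAssignment:
    """Alignment transforms for all segments at the calibration instant."""
    missing = [s for s in SEGMENTS if s not in orientations]
    if missing:
        raise ValueError(f"missing segment orientations: {missing}")
    q_seg0 = derive_initial_frames(orientations["foot"].quat[cal_index])
    seg_initial, sensor_initial, transform = {}, {}, {}
    for seg in SEGMENTS:
        q_sensor0 = orientations[seg].quat[cal_index]
        seg_initial[seg] = q_seg0
        sensor_initial[seg] = np.asarray(q_sensor0, dtype=float)
        transform[seg] = alignment_transform(q_seg0, q_sensor0)
    return SegmentFrameAssignment(seg_initial, sensor_initial, transform)


def compute_joint_angles(
    orientations: dict,
    assignment: SegmentFrameAssignment | None = None,
    cal_index: int | None = None,
    flexion_sign: dict | None = None,
) -> dict:
    """Full angle chain: align each sensor, difference segment pairs.

    Parameters
    ----------
    orientations : dict segment -> OrientationSeries
        Fused sensor orientations for pelvis, thigh, shank, foot on one
        common time base.
    assignment : optional precomputed calibration; derived at ``cal_index``
        (default: auto-detected via a quasi-static heuristic is the caller's
        job; index 0 is used here) when absent.

    Returns dict joint -> :class:`JointAngleSeries`.
    """
    if assignment is None:
        assignment = build_assignment(orientations, cal_index or 0)
    signs = dict(FLEXION_SIGN)
    if flexion_sign:
        signs.update(flexion_sign)
    time = orientations["foot"].time
    seg_q = {
        seg: segment_orientation(orientations[seg].quat, assignment.transform[seg])
        for seg in SEGMENTS
    }
    out = {}
    for joint, (prox, dist) in JOINTS.items():
        qj = joint_angle(seg_q[prox], seg_q[dist])
        flex = flexion_trace(qj, sign=signs[joint])
        out[joint] = JointAngleSeries(joint=joint, time=time, qj=qj, flexion_deg=flex)
    return out


def segment_repetitions(
    series: JointAngleSeries,
    min_rom: float = 20.0,
    min_separation: float = 1.0,
    fs: float | None = None,
) -> list:
    """One window per prominent flexion peak, bounded by adjacent minima.

    Peaks need prominence >= ``min_rom`` degrees; peaks closer than
    ``min_separation`` seconds are merged (the taller one wins).  A trace
    with no qualifying peak yields an empty list.
    """
    flex = np.asarray(series.flexion_deg, dtype=float)
    if fs is None:
        dt = np.median(np.diff(series.time)) if series.time.size > 1 else 1.0
        fs = 1.0 / dt
    distance = max(1, int(round(min_separation * fs)))
    peaks, _ = find_peaks(flex, prominence=min_rom, distance=distance)
    windows: list[RepetitionWindow] = []
    for j, p in enumerate(peaks):
        left = peaks[j - 1] if j > 0 else 0
        right = peaks[j + 1] if j + 1 < len(peaks) else flex.size - 1
        start = left + int(np.argmin(flex[left:p]))
        end = p + int(np.argmin(flex[p : right + 1]))
        if start < p < end:
            windows.append(RepetitionWindow(start=start, peak=p, end=end))
    return windows


def compute_rom(series: JointAngleSeries, windows: list) -> RomSummary:
    """Per-repetition range of motion (max − min flexion) with mean ± SD."""
    if not windows:
        raise ValueError("no repetition windows supplied")
    flex = np.asarray(series.flexion_deg, dtype=float)
    roms = []
    for w in windows:
        if w.start < 0 or w.end >= flex.size:
            raise ValueError(f"window {w} lies outside the series bounds (n={flex.size})")
        seg = flex[w.start : w.end + 1]
        roms.append(float(seg.max() - seg.min()))
    return RomSummary(joint=series.joint, rom_deg=np.array(roms))
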