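"""Gait spatiotemporal chain: event detection from foot acceleration,
stride/stance timing, and zero-velocity-update (ZUPT) stride length.

Event detection works on a smoothed *activity envelope* combining the
deviation of the specific-force magnitude from gravity with the gyro
magnitude.  Sustained envelope elevation marks swing; the final contact
(FC) is the swing onset and the initial contact (IC) the swing
termination.  Each event carries a confidence score reflecting how far
the envelope rose above threshold — FC in particular is ambiguous for
heel-mounted sensors during modified gait, and a low score surfaces that.

Stride length integrates the global-frame linear acceleration (rotated
specific force minus gravity) with a trapezoidal rule.  Integration drift
is corrected at each detected stance — a known instance of zero velocity —
either by a per-stride linear de-drift (the closed-form baseline) or by a
small Kalman estimator of the accelerometer-bias error whose zero-velocity
pseudo-measurements are applied retroactively over each stride.  The
stride length is the horizontal displacement magnitude between
consecutive stance midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .fusion import OrientationSeries
from .preprocess import GRAVITY, MargRecording
from .quatcore import rotate_vector

__all__ = [
    "GaitEventSeries",
    "StanceInterval",
    "StrideMetrics",
    "detect_stance_intervals",
    "detect_gait_events",
    "temporal_metrics",
    "zupt_stride_length",
    "compute_gait_metrics",
]


@dataclass
class GaitEventSeries:
    ic_times: np.ndarray  # (k,) s
    fc_times: np.ndarray  # (m,) s
    ic_confidence: np.ndarray = field(default_factory=lambda: np.array([]))
    fc_confidence: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        for arr in (self.ic_times, self.fc_times):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError("event times must be strictly increasing")


@dataclass
class StanceInterval:
    start: int  # sample index, inclusive
    end: int  # sample index, inclusive

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("stance interval end precedes start")

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class StrideMetrics:
    stride_length_m: np.ndarray
    stride_time_s: np.ndarray
    stance_time_s: np.ndarray

    def __post_init__(self) -> None:
        self.stride_length_m = np.asarray(self.stride_length_m, dtype=float)
        self.stride_time_s = np.asarray(self.stride_time_s, dtype=float)
        self.stance_time_s = np.asarray(self.stance_time_s, dtype=float)
        if np.any(self.stride_length_m < 0):
            raise ValueError("stride length cannot be negative")

    def summary(self) -> dict:
        out = {}
        for name in ("stride_length_m", "stride_time_s", "stance_time_s"):
            v = getattr(self, name)
            out[name] = {
                "n": int(v.size),
                "mean": float(v.mean()) if v.size else float("nan"),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            }
        return out


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    kernel = np.ones(max(1, w)) / max(1, w)
    # Two passes of a centred moving average: zero phase, gentle roll-off.
    return np.convolve(np.convolve(x, kernel, mode="same"), kernel, mode="same")


def _activity_envelope(
    rec: MargRecording,
    smooth_s: float = 0.01,
    detrend_s: float = 2.0,
    rate_deadband: float = 0.25,
) -> np.ndarray:
    """Smoothed movement-intensity signal in accel units (m/s^2 equivalent).

    Combines the deviation of the specific-force magnitude from gravity
    with two gyro terms (rad/s scaled by g): a slow-baseline-removed term
    that is immune to gyro bias drift, and an absolute-rate term with a
    ``rate_deadband`` so sustained fast rotation still registers as
    movement.  Low-passed by a zero-phase double moving average.
    """
    acc_dev = np.abs(np.linalg.norm(rec.accel, axis=1) - GRAVITY)
    w_base = int(round(detrend_s * rec.fs))
    gyro_detr = rec.gyro - np.column_stack([_smooth(rec.gyro[:, i], w_base) for i in range(3)])
    gyr = np.linalg.norm(gyro_detr, axis=1)
    gyr_abs = np.maximum(np.linalg.norm(rec.gyro, axis=1) - rate_deadband, 0.0)
    e = acc_dev + GRAVITY * (gyr + gyr_abs)
    return _smooth(e, int(round(smooth_s * rec.fs)))


def detect_stance_intervals(
    rec: MargRecording,
    thresh: float = 0.5,
    min_duration_s: float = 0.1,
) -> list:
    """Intervals where the foot is effectively still.

    The activity envelope must stay below ``thresh`` (m/s^2 equivalent) for
    at least ``min_duration_s``.  A fully static stream yields one interval
    covering everything; continuous movement yields none.
    """
    env = _activity_envelope(rec)
    still = env < thresh
    need = max(1, int(round(min_duration_s * rec.fs)))
    intervals: list[StanceInterval] = []
    n = still.size
    i = 0
    while i < n:
        if still[i]:
            j = i
            while j + 1 < n and still[j + 1]:
                j += 1
            if j - i + 1 >= need:
                intervals.append(StanceInterval(start=i, end=j))
            i = j + 1
        else:
            i += 1
    return intervals


def detect_gait_events(
    rec: MargRecording,
    orientation: OrientationSeries | None = None,
    thresh: float = 0.5,
    min_swing_s: float = 0.08,
    min_stance_s: float = 0.1,
) -> GaitEventSeries:
    """Initial/final contacts from the foot acceleration signature.

    Swing phases are sustained elevations of the activity envelope; FC is
    the acceleration rise at swing onset, IC the decay at swing termination.
    Confidence is the margin by which the swing's envelope peak clears the
    threshold (saturating at 1), low for timid swings whose contacts are
    ambiguous.
    """
    env = _activity_envelope(rec)
    stances = detect_stance_intervals(rec, thresh=thresh, min_duration_s=min_stance_s)
    if not stances:
        return GaitEventSeries(np.array([]), np.array([]))
    min_swing = max(1, int(round(min_swing_s * rec.fs)))
    ic, fc, ic_conf, fc_conf = [], [], [], []
    for a, b in zip(stances[:-1], stances[1:]):
        if b.start - a.end < min_swing:
            continue  # glitch between stances, not a swing
        peak = float(env[a.end : b.start + 1].max())
        conf = float(min(1.0, (peak / thresh - 1.0) / 4.0))
        fc.append(rec.time[a.end])  # last still sample before swing onset
        fc_conf.append(conf)
        ic.append(rec.time[b.start])  # first still sample after swing
        ic_conf.append(conf)
    if not ic:
        warnings.warn("no gait events detected", stacklevel=2)
    return GaitEventSeries(
        ic_times=np.array(ic),
        fc_times=np.array(fc),
        ic_confidence=np.array(ic_conf),
        fc_confidence=np.array(fc_conf),
    )


def temporal_metrics(events: GaitEventSeries) -> tuple[np.ndarray, np.ndarray]:
    """Stride times (consecutive ICs) and stance times (IC to next FC)."""
    ic = events.ic_times
    fc = events.fc_times
    stride = np.diff(ic) if ic.size >= 2 else np.array([])
    stance = []
    for i, t_ic in enumerate(ic):
        nxt = fc[fc > t_ic]
        upper = ic[i + 1] if i + 1 < ic.size else np.inf
        nxt = nxt[nxt < upper]
        if nxt.size:
            stance.append(nxt[0] - t_ic)
        elif i + 1 < ic.size:
            warnings.warn(f"stride at {t_ic:.3f}s has no matching FC; skipped", stacklevel=2)
    return stride, np.array(stance)


def zupt_stride_length(
    foot_rec: MargRecording,
    orientation: OrientationSeries,
    stances: list,
    correction: str = "kalman",
    direction: np.ndarray | None = None,
    zv_meas_var: float = 1e-4,
    bias_walk_var: float = 2.5e-5,
) -> np.ndarray:
    """Per-stride lengths between consecutive stance midpoints.

    Parameters
    ----------
    correction : {"kalman", "linear", "none"}
        ``linear`` removes the per-stride integration drift by linear
        interpolation of the stance-to-stance velocity error (closed form);
        ``kalman`` additionally tracks an accelerometer-bias error state
        updated by the zero-velocity pseudo-measurement of each stride and
        applied retroactively; ``none`` integrates raw (drift included).
    direction : optional unit 3-vector
        Project displacement onto this horizontal direction of travel (e.g.
        from the initial pelvis heading) instead of taking the horizontal
        displacement magnitude.
    """
    if len(stances) < 2:
        return np.array([])
    if correction not in ("kalman", "linear", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    n = foot_rec.n_samples
    if orientation.quat.shape[0] != n:
        raise ValueError("orientation series does not match the recording length")

    t = foot_rec.time
    a_global = rotate_vector(orientation.quat, foot_rec.accel) - np.array([0.0, 0.0, GRAVITY])
    v_raw = cumulative_trapezoid(a_global, t, axis=0, initial=0.0)

    mids = np.array([s.mid for s in stances])
    lengths = []
    # Accelerometer-bias error estimate shared across strides.
    b_hat = np.zeros(3)
    P = np.full(3, 0.04)  # (m/s^2)^2
    for m0, m1 in zip(mids[:-1], mids[1:]):
        if not np.all(orientation.valid[m0 : m1 + 1]):
            warnings.warn("orientation invalid within stride; skipped", stacklevel=2)
            lengths.append(np.nan)
            continue
        seg_t = t[m0 : m1 + 1]
        dt_span = float(seg_t[-1] - seg_t[0])
        v_seg = v_raw[m0 : m1 + 1]
        if correction == "none":
            v_corr = v_seg
        elif correction == "linear":
            frac = ((seg_t - seg_t[0]) / dt_span)[:, None]
            v_corr = v_seg - v_seg[0] - frac * (v_seg[-1] - v_seg[0])
        else:  # kalman
            P = P + bias_walk_var
            z = (v_seg[-1] - v_seg[0]) / dt_span  # observed mean accel error
            K = P / (P + zv_meas_var / dt_span**2)
            b_hat = b_hat + K * (z - b_hat)
            P = (1.0 - K) * P
            drift = v_seg[0] + b_hat[None, :] * (seg_t - seg_t[0])[:, None]
            v_corr = v_seg - drift
        disp = np.trapezoid(v_corr, seg_t, axis=0)
        if direction is not None:
            d = np.asarray(direction, dtype=float)
            d = np.array([d[0], d[1], 0.0])
            d /= np.linalg.norm(d)
            lengths.append(abs(float(disp @ d)))
        else:
            lengths.append(float(np.hypot(disp[0], disp[1])))
    return np.array(lengths)


def compute_gait_metrics(
    foot_rec: MargRecording,
    orientation: OrientationSeries,
    correction: str = "kalman",
    direction: np.ndarray | None = None,
) -> StrideMetrics:
    """Events, timing, and ZUPT stride lengths in one pass."""
    events = detect_gait_events(foot_rec)
    stride_t, stance_t = temporal_metrics(events)
    stances = detect_stance_intervals(foot_rec)
    lengths = zupt_stride_length(foot_rec, orientation, stances, correction=correction, direction=direction)
    return StrideMetrics(
        stride_length_m=lengths[~np.isnan(lengths)] if lengths.size else lengths,
        stride_time_s=stride_t,
        stance_time_s=stance_t,
    )
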