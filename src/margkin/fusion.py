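"""Orientation estimation: an error-state (indirect) Kalman AHRS.

The filter propagates a nominal orientation quaternion by gyroscope
integration and maintains a 9-dimensional error state

    x = [ attitude error (sensor frame, rad),
          gyro bias error (rad/s),
          linear-acceleration error (global frame, m/s^2) ]

corrected at every sample by gravity (accelerometer) and heading
(magnetometer) observations.  The tuning variances map directly onto the
filter matrices:

* gyro noise variance        -> attitude process noise per step
* gyro offset drift variance -> bias random-walk intensity
* accel noise variance       -> accelerometer measurement noise
* mag disturbance (+ instrument) noise -> magnetometer measurement noise
* linear-acceleration compensation factor in [0, 1] -> per-sample decay of
  the linear-acceleration state: body acceleration is modeled as a
  first-order process a_k+1 = c * a_k + w, so accelerometer innovations
  during dynamic movement are attributed to body acceleration rather than
  dragged into attitude.

The global frame is z-up with x along magnetic north (the horizontal
component of the calibrated field at initialization), shared by every
sensor fused against the same field — which is what makes per-segment
orientations comparable when differencing them into joint angles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import GRAVITY, MargRecording, PipelineConfig
from .quatcore import hamilton, normalize, quat_to_dcm

__all__ = ["OrientationSeries", "estimate_orientation", "estimate_static_bias", "initial_orientation"]


@dataclass
class OrientationSeries:
    """Time-indexed sensor-to-global unit quaternions with validity flags."""

    time: np.ndarray  # (n,) s
    quat: np.ndarray  # (n, 4) scalar-first, sensor frame -> global frame
    valid: np.ndarray  # (n,) bool; False where the estimate has degraded confidence
    segment: str = "unknown"
    final_covariance: np.ndarray | None = None  # (9, 9) error-state covariance at the last step


def _quat_step(qw, qx, qy, qz, wx, wy, wz, dt):
    """Right-multiply q by the incremental rotation exp([w*dt]/2)."""
    ang = np.sqrt(wx * wx + wy * wy + wz * wz) * dt
    if ang < 1e-12:
        dw, s = 1.0, 0.5 * dt
    else:
        dw = np.cos(0.5 * ang)
        s = np.sin(0.5 * ang) / (ang / dt)  # sin(ang/2)/|w|
    dx, dy, dz = wx * s, wy * s, wz * s
    rw = qw * dw - qx * dx - qy * dy - qz * dz
    rx = qw * dx + qx * dw + qy * dz - qz * dy
    ry = qw * dy - qx * dz + qy * dw + qz * dx
    rz = qw * dz + qx * dy - qy * dx + qz * dw
    n = np.sqrt(rw * rw + rx * rx + ry * ry + rz * rz)
    return rw / n, rx / n, ry / n, rz / n


def _dcm(qw, qx, qy, qz):
    R = np.empty((3, 3))
    R[0, 0] = 1 - 2 * (qy * qy + qz * qz)
    R[0, 1] = 2 * (qx * qy - qw * qz)
    R[0, 2] = 2 * (qx * qz + qw * qy)
    R[1, 0] = 2 * (qx * qy + qw * qz)
    R[1, 1] = 1 - 2 * (qx * qx + qz * qz)
    R[1, 2] = 2 * (qy * qz - qw * qx)
    R[2, 0] = 2 * (qx * qz - qw * qy)
    R[2, 1] = 2 * (qy * qz + qw * qx)
    R[2, 2] = 1 - 2 * (qx * qx + qy * qy)
    return R


def _esk_loop(
    accel,
    gyro,
    mag,
    dt,
    q0,
    b0,
    m_ref,
    g,
    var_gyro,
    var_drift,
    var_acc,
    var_mag,
    comp,
    var_lin,
    use_corrections,
):
    n = accel.shape[0]
    out = np.empty((n, 4))
    qw, qx, qy, qz = q0[0], q0[1], q0[2], q0[3]
    bias = b0.copy()
    alin = np.zeros(3)  # global-frame linear acceleration estimate

    P = np.zeros((9, 9))
    for i in range(3):
        P[i, i] = 1e-4
        P[3 + i, 3 + i] = 2.5e-3
        P[6 + i, 6 + i] = var_lin / max(1.0 - comp * comp, 1e-3)

    I9 = np.eye(9)
    g_vec = np.array([0.0, 0.0, g])
    q_att = var_gyro * dt * dt

    for k in range(n):
        wx = gyro[k, 0] - bias[0]
        wy = gyro[k, 1] - bias[1]
        wz = gyro[k, 2] - bias[2]
        qw, qx, qy, qz = _quat_step(qw, qx, qy, qz, wx, wy, wz, dt)

        if use_corrections:
            alin = comp * alin

            # F = d(error)/d(error): attitude error rotates with -[w]x, is
            # driven by bias error; lin-accel error decays with comp.
            F = I9.copy()
            F[0, 1] = wz * dt
            F[0, 2] = -wy * dt
            F[1, 0] = -wz * dt
            F[1, 2] = wx * dt
            F[2, 0] = wy * dt
            F[2, 1] = -wx * dt
            for i in range(3):
                F[i, 3 + i] = -dt
                F[6 + i, 6 + i] = comp
            P = F @ P @ F.T
            q_lin = var_lin * comp * comp
            for i in range(3):
                P[i, i] += q_att
                P[3 + i, 3 + i] += var_drift
                P[6 + i, 6 + i] += q_lin

            R = _dcm(qw, qx, qy, qz)

            # --- accelerometer (gravity + linear acceleration) update ---
            fg = g_vec + alin
            fs = R.T @ fg  # predicted specific force, sensor frame
            y = accel[k] - fs
            # Adaptive linear-acceleration protection: innovation energy in
            # excess of the measurement noise is treated as body acceleration
            # in proportion to comp^2, shielding attitude during dynamics
            # while leaving quasi-static corrections at full strength.
            excess = (y[0] * y[0] + y[1] * y[1] + y[2] * y[2]) / 3.0 - var_acc
            if excess > 0.0:
                boost = comp * comp * excess
                for i in range(3):
                    P[6 + i, 6 + i] += boost
            H = np.zeros((3, 9))
            # [fs]x block on attitude error
            H[0, 1] = -fs[2]
            H[0, 2] = fs[1]
            H[1, 0] = fs[2]
            H[1, 2] = -fs[0]
            H[2, 0] = -fs[1]
            H[2, 1] = fs[0]
            H[:, 6:9] = R.T
            S = H @ P @ H.T
            for i in range(3):
                S[i, i] += var_acc
            K = P @ H.T @ np.linalg.inv(S)
            dx = K @ y
            P = (I9 - K @ H) @ P
            qw, qx, qy, qz = _quat_step(qw, qx, qy, qz, dx[0] / dt, dx[1] / dt, dx[2] / dt, dt)
            bias[0] += dx[3]
            bias[1] += dx[4]
            bias[2] += dx[5]
            alin[0] += dx[6]
            alin[1] += dx[7]
            alin[2] += dx[8]

            # --- magnetometer (heading) update ---
            R = _dcm(qw, qx, qy, qz)
            ms = R.T @ m_ref
            y = mag[k] - ms
            H = np.zeros((3, 9))
            H[0, 1] = -ms[2]
            H[0, 2] = ms[1]
            H[1, 0] = ms[2]
            H[1, 2] = -ms[0]
            H[2, 0] = -ms[1]
            H[2, 1] = ms[0]
            S = H @ P @ H.T
            for i in range(3):
                S[i, i] += var_mag
            K = P @ H.T @ np.linalg.inv(S)
            dx = K @ y
            P = (I9 - K @ H) @ P
            qw, qx, qy, qz = _quat_step(qw, qx, qy, qz, dx[0] / dt, dx[1] / dt, dx[2] / dt, dt)
            bias[0] += dx[3]
            bias[1] += dx[4]
            bias[2] += dx[5]
            alin[0] += dx[6]
            alin[1] += dx[7]
            alin[2] += dx[8]

            P = 0.5 * (P + P.T)

        out[k, 0] = qw
        out[k, 1] = qx
        out[k, 2] = qy
        out[k, 3] = qz
    return out, P


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _quat_step = njit(cache=True)(_quat_step)
    _dcm = njit(cache=True)(_dcm)
    _esk_loop = njit(cache=True)(_esk_loop)
except ImportError:  # pragma: no cover
    pass


def initial_orientation(accel0: np.ndarray, mag0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Attitude from mean specific force, heading from the calibrated field.

    Returns ``(q0, m_ref)``: the initial sensor-to-global quaternion and the
    global-frame field reference (z-up, x = magnetic north) consistent with
    the supplied quasi-static means.
    """
    a = np.asarray(accel0, dtype=float)
    m = np.asarray(mag0, dtype=float)
    na = np.linalg.norm(a)
    if na < 1e-6:
        raise ValueError("initialization window has near-zero specific force")
    u = a / na  # sensor-frame direction of global +z
    e3 = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, e3)
    c = float(u @ e3)
    if np.linalg.norm(v) < 1e-12:
        R0 = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R0 = np.eye(3) + vx + vx @ vx / (1.0 + c)  # rotates u onto e3
    m1 = R0 @ m
    psi = np.arctan2(m1[1], m1[0])
    cz, sz = np.cos(-psi), np.sin(-psi)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    R = Rz @ R0  # sensor -> global DCM: third row = u, heading along mag north
    m_ref = R @ m
    m_ref[1] = 0.0  # exact by construction; clamp numerical residue
    from .quatcore import dcm_to_quat

    return dcm_to_quat(R), m_ref


def estimate_orientation(
    rec: MargRecording,
    config: PipelineConfig,
    init: np.ndarray | None = None,
    gyro_only: bool = False,
    init_bias: bool = True,
) -> OrientationSeries:
    """Run the error-state Kalman AHRS over a preprocessed recording.

    Parameters
    ----------
    rec : MargRecording
        Streams already conditioned (mag calibrated and on the IMU time base).
    config : PipelineConfig
        Noise variances and the linear-acceleration compensation factor.
    init : optional quaternion
        Overrides the quasi-static attitude/heading initialization.
    gyro_only : bool
        Disable accelerometer/magnetometer corrections and bias handling —
        pure angular-rate integration (for drift demonstrations).
    init_bias : bool
        Estimate the gyro bias as the mean rate over the initialization
        window (assumed quasi-static), mirroring static-dataset tuning.
    """
    if rec.mag_time is not None:
        raise ValueError("magnetometer must be resampled onto the IMU time base first")
    n = rec.n_samples
    if n < 2:
        raise ValueError("recording too short to fuse")
    dt = 1.0 / rec.fs

    n_init = max(2, min(n, int(round(config.init_window_s * rec.fs))))
    a_mean = rec.accel[:n_init].mean(axis=0)
    m_mean = rec.mag[:n_init].mean(axis=0)

    if init is not None:
        q0 = normalize(np.asarray(init, dtype=float))
        m_ref = quat_to_dcm(q0) @ m_mean
    else:
        q0, m_ref = initial_orientation(a_mean, m_mean)

    b0 = np.zeros(3)
    if init_bias and not gyro_only:
        gm = rec.gyro[:n_init]
        if np.all(np.linalg.norm(gm, axis=1) < 0.2):  # plausible quasi-static window
            b0 = gm.mean(axis=0)

    var_mag = config.mag_disturbance_var + config.mag_noise_var
    quat, P_final = _esk_loop(
        np.ascontiguousarray(rec.accel),
        np.ascontiguousarray(rec.gyro),
        np.ascontiguousarray(rec.mag),
        dt,
        np.asarray(q0, dtype=float),
        b0,
        np.asarray(m_ref, dtype=float),
        GRAVITY,
        config.gyro_noise_var,
        config.gyro_drift_var,
        config.accel_noise_var,
        var_mag,
        config.lin_accel_comp,
        config.lin_accel_process_var,
        not gyro_only,
    )

    # Free-fall / sensor-failure artifact: near-zero specific force carries no
    # attitude information; flag those spans as degraded confidence.
    valid = np.linalg.norm(rec.accel, axis=1) > 0.5
    if not valid.all():
        warnings.warn("near-zero specific force detected; validity degraded on flagged samples", stacklevel=2)
    return OrientationSeries(
        time=rec.time.copy(), quat=quat, valid=valid, segment=rec.segment, final_covariance=P_final
    )


def estimate_static_bias(
    rec: MargRecording,
    max_rate: float = 0.1,
    max_accel_dev: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gyro bias (and per-axis variance) from a verified static window.

    Rejects the window if any gyro sample exceeds ``max_rate`` rad/s or the
    specific-force magnitude strays more than ``max_accel_dev`` m/s^2 from g.
    """
    g = np.asarray(rec.gyro, dtype=float)
    if np.any(np.abs(g) > max_rate):
        raise ValueError(f"motion detected: gyro exceeds {max_rate} rad/s within the window")
    acc_mag = np.linalg.norm(rec.accel, axis=1)
    if np.any(np.abs(acc_mag - GRAVITY) > max_accel_dev):
        raise ValueError("motion detected: specific force deviates from gravity within the window")
    return g.mean(axis=0), g.var(axis=0, ddof=1)
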