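"""Raw MARG stream conditioning: containers, magnetometer hard/soft-iron
calibration, gyroscope low-pass filtering, and rate reconciliation.

Two named processing configurations are provided:

* ``DEF`` — default fusion-filter tuning, no gyroscope filtering;
* ``TAF`` — tuned noise variances plus a 6th-order 60 Hz low-pass
  Butterworth filter on the gyroscope stream (applied forward-backward,
  so the effective attenuation is that of two order-6 passes and the
  phase delay is zero — event timing downstream is preserved).

Acceleration is never filtered in either configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

GRAVITY = 9.81  # m/s^2

# Sensor full-scale ranges of the target device class.
ACCEL_RANGE = 16 * GRAVITY  # ±16 g, m/s^2
GYRO_RANGE = np.deg2rad(2000.0)  # ±2000 °/s, rad/s
MAG_RANGE = 4900.0  # ±4900 µT

IMU_RATE_HZ = 1125.0
MAG_RATE_HZ = 112.5


@dataclass
class MargRecording:
    """Per-segment tri-axial MARG streams on a uniform IMU time base.

    accel/gyro are sampled at ``fs`` (nominally 1125 Hz); the magnetometer
    runs at a tenth of that on its own time stamps until
    :func:`resample_mag_to_imu` places it on the IMU base.
    """

    time: np.ndarray  # (n,) s, uniform, monotone
    accel: np.ndarray  # (n, 3) m/s^2, specific force in the sensor frame
    gyro: np.ndarray  # (n, 3) rad/s
    mag: np.ndarray  # (m, 3) µT
    mag_time: np.ndarray | None = None  # (m,) s; None once mag is on the IMU base
    segment: str = "unknown"
    clipped: int = 0  # count of samples clipped to the sensor range

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        n = self.time.size
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel/gyro must share the IMU time base (n, 3)")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time stamps must be strictly increasing")
        if self.mag_time is not None:
            self.mag_time = np.asarray(self.mag_time, dtype=float)
            if self.mag.shape != (self.mag_time.size, 3):
                raise ValueError("mag and mag_time lengths disagree")
        elif self.mag.shape != (n, 3):
            raise ValueError("mag without mag_time must be on the IMU time base")
        self._clip_to_range()

    def _clip_to_range(self) -> None:
        # Out-of-range samples are clipped (not dropped) to keep the time base
        # uniform; the count is surfaced for diagnostics.
        clipped = 0
        for arr, lim in ((self.accel, ACCEL_RANGE), (self.gyro, GYRO_RANGE), (self.mag, MAG_RANGE)):
            over = np.abs(arr) > lim
            clipped += int(over.sum())
            np.clip(arr, -lim, lim, out=arr)
        if clipped:
            warnings.warn(f"{clipped} samples outside sensor range were clipped", stacklevel=3)
        self.clipped = clipped

    @property
    def fs(self) -> float:
        if self.time.size < 2:
            return IMU_RATE_HZ
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass
class MagCalibration:
    """Hard-iron offset and symmetric positive-definite soft-iron correction.

    ``corrected = soft_iron @ (raw - offset)``.  The soft-iron matrix is
    normalized to unit determinant so that ``field_strength`` carries the
    fitted field magnitude.
    """

    offset: np.ndarray  # (3,) µT
    soft_iron: np.ndarray  # (3, 3), SPD, det = 1
    field_strength: float  # µT


@dataclass
class PipelineConfig:
    """Fusion and filtering knobs for one processing configuration.

    The noise variances act as the process/measurement noise of the
    orientation filter; the linear-acceleration compensation factor (in
    [0, 1]) is the per-sample decay of the filter's linear-acceleration
    state — larger values model more persistent body acceleration.
    """

    mode: str = "TAF"
    gyro_filter_enabled: bool = True
    gyro_filter_order: int = 6
    gyro_filter_cutoff_hz: float = 60.0
    accel_noise_var: float = 3.45e-4  # (m/s^2)^2
    gyro_noise_var: float = 1.40e-6  # (rad/s)^2
    gyro_drift_var: float = 1.77e-8  # (rad/s)^2 per-sample bias random walk
    mag_disturbance_var: float = 0.1  # µT^2
    lin_accel_comp: float = 0.9  # [0, 1]
    expected_field_ut: float | None = None  # None: take from the mag calibration
    # Package-internal filter knobs (not part of the published tuning set).
    mag_noise_var: float = 0.1  # µT^2 instrument noise on top of disturbance
    lin_accel_process_var: float = 0.5  # (m/s^2)^2 baseline drive of the lin-accel state
    init_window_s: float = 0.5  # quasi-static span used to initialize attitude

    def __post_init__(self) -> None:
        if not 0.0 <= self.lin_accel_comp <= 1.0:
            raise ValueError("linear-acceleration compensation factor must lie in [0, 1]")

    def resolve_field(self, cal: MagCalibration | None = None) -> float:
        if self.expected_field_ut is not None:
            return self.expected_field_ut
        if cal is not None:
            return cal.field_strength
        return 50.0


def _def_preset() -> PipelineConfig:
    return PipelineConfig(
        mode="DEF",
        gyro_filter_enabled=False,
        accel_noise_var=1.92e-3,
        gyro_noise_var=9.14e-4,
        gyro_drift_var=3.05e-13,
        mag_disturbance_var=0.5,
        lin_accel_comp=0.5,
        expected_field_ut=50.0,
    )


def _taf_preset() -> PipelineConfig:
    return PipelineConfig(
        mode="TAF",
        gyro_filter_enabled=True,
        gyro_filter_order=6,
        gyro_filter_cutoff_hz=60.0,
        accel_noise_var=3.45e-4,
        gyro_noise_var=1.40e-6,
        gyro_drift_var=1.77e-8,
        mag_disturbance_var=0.1,
        lin_accel_comp=0.9,
        expected_field_ut=None,
    )


PRESETS = {"DEF": _def_preset, "TAF": _taf_preset}


def get_config(name_or_cfg: "str | PipelineConfig", **overrides) -> PipelineConfig:
    """Resolve a named preset (``"DEF"``/``"TAF"``) or pass a config through."""
    if isinstance(name_or_cfg, PipelineConfig):
        cfg = name_or_cfg
    else:
        key = str(name_or_cfg).upper()
        if key not in PRESETS:
            raise KeyError(f"unknown configuration {name_or_cfg!r}; expected one of {sorted(PRESETS)}")
        cfg = PRESETS[key]()
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Magnetometer calibration
# ---------------------------------------------------------------------------

def fit_mag_calibration(raw_mag: np.ndarray, min_spread_ut: float = 10.0) -> MagCalibration:
    """Ellipsoid-to-sphere hard/soft-iron calibration.

    Fits the general quadric ``m^T M m + b^T m = 1`` to the raw readings by
    linear least squares, then factors the recentred ellipsoid shape matrix
    into a symmetric positive-definite soft-iron correction with unit
    determinant.  The fitted field magnitude is the geometric-mean radius
    of the ellipsoid.

    Parameters
    ----------
    raw_mag : (n, 3) array, µT
        Readings spanning diverse orientations (n >= 100 recommended).
    min_spread_ut : float
        Minimum per-axis min-max spread; guards against degenerate,
        near-planar point clouds that make the fit ill-posed.
    """
    m = np.asarray(raw_mag, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3 or m.shape[0] < 12:
        raise ValueError("need an (n, 3) array with n >= 12 magnetometer samples")
    spread = m.max(axis=0) - m.min(axis=0)
    if np.any(spread < min_spread_ut):
        raise ValueError(
            "magnetometer samples do not span enough orientations "
            f"(per-axis spread {spread.round(2)} µT < {min_spread_ut} µT); "
            "rotate the sensor through all attitudes and refit"
        )
    # Planarity guard: the smallest principal extent must be a meaningful
    # fraction of the largest, otherwise the quadric is unconstrained.
    centered = m - m.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 0.05 * sv[0]:
        raise ValueError("magnetometer point cloud is nearly planar; coverage insufficient for an ellipsoid fit")

    x, y, z = m.T
    D = np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, x, y, z])
    p, *_ = np.linalg.lstsq(D, np.ones(m.shape[0]), rcond=None)
    A, B, C, Dxy, Exz, Fyz, G, H, I = p
    M = np.array([[A, Dxy, Exz], [Dxy, B, Fyz], [Exz, Fyz, C]])
    b = np.array([G, H, I])
    eigvals = np.linalg.eigvalsh(M)
    if np.any(eigvals <= 0):
        raise ValueError("quadric fit is not an ellipsoid; check coverage and disturbances")
    center = -0.5 * np.linalg.solve(M, b)
    k = 1.0 + 0.25 * b @ np.linalg.solve(M, b)
    S = M / k  # (m - c)^T S (m - c) = 1
    # Symmetric square root of the shape matrix.
    w, V = np.linalg.eigh(S)
    sqrtS = (V * np.sqrt(w)) @ V.T
    field = float(np.prod(w) ** (-1.0 / 6.0))  # geometric-mean semi-axis
    soft_iron = field * sqrtS  # det = 1 by construction
    return MagCalibration(offset=center, soft_iron=soft_iron, field_strength=field)


def apply_mag_calibration(mag: np.ndarray, cal: MagCalibration) -> np.ndarray:
    """Correct raw magnetometer readings: ``soft_iron @ (raw - offset)``."""
    m = np.asarray(mag, dtype=float)
    return (m - cal.offset) @ cal.soft_iron.T


# ---------------------------------------------------------------------------
# Gyro filtering and rate reconciliation
# ---------------------------------------------------------------------------

def filter_gyro(gyro: np.ndarray, config: PipelineConfig, fs: float = IMU_RATE_HZ) -> np.ndarray:
    """Low-pass the gyroscope stream per the configuration.

    Returns the input unchanged when the configuration disables filtering
    (the DEF path).  Zero-phase (forward-backward) Butterworth otherwise.
    """
    g = np.asarray(gyro, dtype=float)
    if not config.gyro_filter_enabled:
        return g
    if config.gyro_filter_cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {config.gyro_filter_cutoff_hz} Hz is at or above Nyquist ({fs / 2} Hz)")
    sos = signal.butter(config.gyro_filter_order, config.gyro_filter_cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, g, axis=0)


def resample_mag_to_imu(rec: MargRecording) -> MargRecording:
    """Linearly interpolate the magnetometer onto the IMU time base.

    End points are held (constant extrapolation); linear interpolation is
    adequate for a 112.5 Hz measurement of a slowly varying field.
    """
    if rec.mag_time is None:
        return rec
    if rec.mag.shape[0] == 0:
        raise ValueError("magnetometer stream is empty; cannot resample")
    mag_up = np.column_stack(
        [np.interp(rec.time, rec.mag_time, rec.mag[:, i]) for i in range(3)]
    )
    return MargRecording(
        time=rec.time,
        accel=rec.accel,
        gyro=rec.gyro,
        mag=mag_up,
        mag_time=None,
        segment=rec.segment,
    )


def preprocess_recording(
    rec: MargRecording,
    config: PipelineConfig,
    mag_cal: MagCalibration | None = None,
) -> MargRecording:
    """Full conditioning pass: mag calibration, gyro filter, rate reconciliation."""
    mag = apply_mag_calibration(rec.mag, mag_cal) if mag_cal is not None else rec.mag
    out = MargRecording(
        time=rec.time,
        accel=rec.accel,
        gyro=filter_gyro(rec.gyro, config, fs=rec.fs),
        mag=mag,
        mag_time=rec.mag_time,
        segment=rec.segment,
    )
    return resample_mag_to_imu(out)
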