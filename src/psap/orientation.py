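"""Sensor-to-body frame alignment and gravity removal.

Sensors strapped to the body are never mounted flush with the anatomical
axes (spine curvature tilts a back-worn unit, an ankle unit sits wherever
the strap lands). Before any metric is computed each sensor is virtually
rotated into the pelvis-aligned frame — X anterior (+AP), Y leftward
(+ML), Z up — and gravity is subtracted, leaving the free (true)
acceleration of the body segment.

Tilt (roll/pitch) is observable from the accelerometer while the subject
stands still: the mean specific-force vector is gravity, and the shortest
rotation taking it onto +Z levels the sensor. Heading (yaw) is not
observable without trusting the magnetometer — which we deliberately do
not, since the metrics downstream are heading-invariant once every site
shares the pelvis frame — so yaw is pinned to zero. When the device
provides its own orientation quaternions they are used instead, taken at
the calibration instant, with the pelvis quaternion defining the shared
reference heading.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .datamodel import G, ConfigError, DataError, ImuRecording, SensorSet


@dataclass
class FreeAcceleration:
    """Gravity-free acceleration in the pelvis-aligned frame (m/s^2)."""

    time: np.ndarray
    acc_free: np.ndarray  # (n, 3): X=AP, Y=ML, Z=vertical


@dataclass
class FrameAlignment:
    """Per-site rotations taking sensor-frame vectors into the aligned frame."""

    to_aligned: dict = field(default_factory=dict)  # site -> Rotation
    relative: dict = field(default_factory=dict)    # site -> Rotation (sensor -> pelvis sensor frame)
    g: float = G

    def sites(self):
        return list(self.to_aligned)


def _tilt_rotation(acc_mean: np.ndarray) -> Rotation:
    """Shortest-arc rotation mapping ``acc_mean`` onto +Z (zero yaw)."""
    a = np.asarray(acc_mean, float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise DataError("zero mean accelerometer vector; cannot estimate tilt")
    a = a / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(a, z), -1.0, 1.0))
    axis = np.cross(a, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        # upside-down: rotate 180 deg about X
        return Rotation.from_rotvec([np.pi, 0.0, 0.0])
    return Rotation.from_rotvec(axis / s * np.arctan2(s, c))


def estimate_static_orientation(
    rec: ImuRecording,
    window: tuple[float, float],
    static_gyro_rms_max: float = 5.0,
) -> Rotation:
    """Tilt of a sensor from a static window, as a sensor-to-level rotation.

    The window must span at least 1 s and be quiet (gyro RMS below
    ``static_gyro_rms_max`` deg/s); otherwise the estimate would mix body
    motion into the gravity direction.
    """
    start, end = window
    if end - start < 1.0:
        raise ConfigError("calibration window must span at least 1 s")
    seg = rec.slice_seconds(start, end)
    gyro_rms = float(np.sqrt(np.mean(seg.gyro ** 2)))
    if gyro_rms > static_gyro_rms_max:
        raise DataError(
            f"window is not static (gyro RMS {gyro_rms:.1f} deg/s > "
            f"{static_gyro_rms_max}); choose a quiet window"
        )
    return _tilt_rotation(seg.acc.mean(axis=0))


def _quat_at(rec: ImuRecording, t: float) -> Rotation:
    idx = int(np.argmin(np.abs(rec.time - t)))
    w, x, y, z = rec.quat[idx]
    return Rotation.from_quat([x, y, z, w])  # scipy is (x, y, z, w)


def build_alignment(
    sset: SensorSet,
    calib_window: tuple[float, float],
    use_device_quaternions: bool = True,
    static_gyro_rms_max: float = 5.0,
) -> FrameAlignment:
    """Build per-site rotations into the pelvis-aligned frame.

    With device quaternions (and ``use_device_quaternions``), the relative
    rotation of each site with respect to the pelvis sensor is taken from
    the quaternions at the calibration instant (the window midpoint), and
    the pelvis tilt estimated from its static accelerometer levels the
    whole bundle. Without them, each site is leveled independently from its
    own static accelerometer mean, which fixes roll and pitch and pins yaw
    to zero.
    """
    if "pelvis" not in sset:
        raise ConfigError("pelvis sensor is required as the reference frame")
    align = FrameAlignment()
    t_mid = 0.5 * (calib_window[0] + calib_window[1])
    pelvis = sset["pelvis"]
    have_quats = use_device_quaternions and all(
        rec.quat is not None for rec in sset.sensors.values()
    )
    pelvis_tilt = estimate_static_orientation(
        pelvis, calib_window, static_gyro_rms_max
    )
    if have_quats:
        r_pelvis = _quat_at(pelvis, t_mid)
        for site, rec in sset.sensors.items():
            rel = r_pelvis.inv() * _quat_at(rec, t_mid)
            align.relative[site] = rel
            align.to_aligned[site] = pelvis_tilt * rel
    else:
        for site, rec in sset.sensors.items():
            tilt = estimate_static_orientation(rec, calib_window, static_gyro_rms_max)
            align.relative[site] = pelvis_tilt.inv() * tilt
            align.to_aligned[site] = tilt
    return align


def remove_gravity(rec: ImuRecording, align: FrameAlignment, site: str) -> FreeAcceleration:
    """Rotate a recording into the aligned frame and subtract gravity."""
    if site not in align.to_aligned:
        raise ConfigError(f"no alignment for site {site!r}")
    rot = align.to_aligned[site]
    acc_aligned = rot.apply(rec.acc)
    acc_aligned[:, 2] -= align.g
    return FreeAcceleration(time=rec.time, acc_free=acc_aligned)


def aligned_gyro(rec: ImuRecording, align: FrameAlignment, site: str) -> np.ndarray:
    """Angular velocity rotated into the aligned frame, deg/s."""
    if site not in align.to_aligned:
        raise ConfigError(f"no alignment for site {site!r}")
    return align.to_aligned[site].apply(rec.gyro)
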