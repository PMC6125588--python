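"""Core data containers for body-worn inertial sensor trials.

A trial is a bundle of per-site IMU recordings (head, trunk, pelvis and
both ankles) sampled on a common uniform grid, plus metadata describing
the subject, session, test protocol and named task phases.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

SITES = ("head", "trunk", "pelvis", "left_ankle", "right_ankle")
UPPER_BODY_SITES = ("head", "trunk", "pelvis")
SESSIONS = ("pre", "in_first", "in_last", "post")
TESTS = ("tandem", "prone_to_stand", "snow")

#: standard gravity, m/s^2
G = 9.80665


class DataError(ValueError):
    """A recording violates a structural invariant (timing, lengths, units)."""


class FormatError(ValueError):
    """A file on disk does not match the expected dialect."""


class ConfigError(ValueError):
    """A configuration or parameter value is invalid for the requested task."""


@dataclass
class ImuRecording:
    """One sensor's synchronized multi-channel time series.

    Attributes
    ----------
    time : (n,) seconds from trial start, uniform grid.
    acc : (n, 3) specific force in m/s^2 (gravity included).
    gyro : (n, 3) angular velocity in deg/s.
    mag : optional (n, 3) magnetic field, arbitrary units.
    quat : optional (n, 4) unit quaternion (w, x, y, z), sensor-to-world.
    rate_hz : sampling frequency.
    """

    time: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    rate_hz: float
    mag: Optional[np.ndarray] = None
    quat: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        if self.quat is not None:
            self.quat = np.asarray(self.quat, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_samples else 0.0

    def validate(self) -> None:
        n = len(self.time)
        if n == 0:
            raise DataError("empty recording")
        for name in ("acc", "gyro"):
            ch = getattr(self, name)
            if ch.shape != (n, 3):
                raise DataError(f"{name} shape {ch.shape} != ({n}, 3)")
        if self.mag is not None and self.mag.shape != (n, 3):
            raise DataError(f"mag shape {self.mag.shape} != ({n}, 3)")
        if self.quat is not None:
            if self.quat.shape != (n, 4):
                raise DataError(f"quat shape {self.quat.shape} != ({n}, 4)")
            norms = np.linalg.norm(self.quat, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise DataError("quaternion rows must have unit norm (tol 1e-6)")
        if not self.rate_hz > 0:
            raise DataError(f"rate_hz must be positive, got {self.rate_hz}")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise DataError("time must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.rate_hz) > 1e-6):
                raise DataError(
                    f"time step deviates from 1/{self.rate_hz} Hz by more than 1e-6 s"
                )

    def slice_seconds(self, start: float, end: float) -> "ImuRecording":
        """Return the samples with start <= t < end (half-open)."""
        m = (self.time >= start) & (self.time < end)
        if not m.any():
            raise DataError(f"window [{start}, {end}) contains no samples")
        return ImuRecording(
            time=self.time[m],
            acc=self.acc[m],
            gyro=self.gyro[m],
            mag=self.mag[m] if self.mag is not None else None,
            quat=self.quat[m] if self.quat is not None else None,
            rate_hz=self.rate_hz,
        )


@dataclass
class TrialMeta:
    """Metadata for one trial: who, when, which test, which condition."""

    subject_id: str
    cohort: str  # crew | control
    session: str  # pre | in_first | in_last | post
    days_elapsed: float
    test: str  # tandem | prone_to_stand | snow
    vision: str = "EO"  # EO | EC
    leg: str = "none"  # left | right | none
    heel: str = "none"  # air | ground | none
    trial_index: int = 1
    phases: dict = field(default_factory=dict)  # name -> (start_s, end_s)

    def __post_init__(self) -> None:
        if self.cohort not in ("crew", "control"):
            raise DataError(f"unknown cohort {self.cohort!r}")
        if self.session not in SESSIONS:
            raise DataError(f"unknown session {self.session!r}")
        if self.test not in TESTS:
            raise DataError(f"unknown test {self.test!r}")
        if self.days_elapsed < 0:
            raise DataError("days_elapsed must be >= 0")
        if self.trial_index < 1:
            raise DataError("trial_index must be >= 1")
        self.phases = {k: (float(a), float(b)) for k, (a, b) in self.phases.items()}
        for name, (a, b) in self.phases.items():
            if b < a:
                raise DataError(f"phase {name!r} ends before it starts")

    @property
    def session_index(self) -> int:
        return SESSIONS.index(self.session) + 1

    def condition_label(self) -> str:
        """Compact condition string, e.g. ``EC`` or ``EC|left|air``."""
        parts = [self.vision]
        if self.leg != "none":
            parts.append(self.leg)
        if self.heel != "none":
            parts.append(self.heel)
        return "|".join(parts)

    def phase(self, name: str) -> tuple[float, float]:
        if name not in self.phases:
            raise ConfigError(f"trial has no {name!r} phase (has {sorted(self.phases)})")
        return self.phases[name]


@dataclass
class SensorSet:
    """The five-site recording bundle for one trial."""

    sensors: dict
    meta: TrialMeta

    def __post_init__(self) -> None:
        if not self.sensors:
            raise DataError("sensor map is empty")
        for site in self.sensors:
            if site not in SITES:
                raise DataError(f"unknown sensor site {site!r}")

    @property
    def rate_hz(self) -> float:
        return next(iter(self.sensors.values())).rate_hz

    def __getitem__(self, site: str) -> ImuRecording:
        return self.sensors[site]

    def __contains__(self, site: str) -> bool:
        return site in self.sensors

    def sites(self) -> list:
        return [s for s in SITES if s in self.sensors]


@dataclass
class MetricRow:
    """One (subject, session, test, condition, variable, value) record."""

    subject_id: str
    cohort: str
    session: str
    days_elapsed: float
    test: str
    condition: str
    variable: str
    value: float
    units: str

    @staticmethod
    def to_frame(rows) -> pd.DataFrame:
        cols = [
            "subject_id", "cohort", "session", "days_elapsed",
            "test", "condition", "variable", "value", "units",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rows],
                            columns=cols)


def replace_meta(s: SensorSet, **kw) -> SensorSet:
    """Return a copy of ``s`` with metadata fields replaced."""
    return SensorSet(sensors=dict(s.sensors), meta=replace(s.meta, **kw))
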