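"""Trial I/O: one CSV per sensor plus a JSON manifest per trial.

The on-disk dialect is deliberately plain so trials can be inspected and
diffed: CSV columns ``t,ax,ay,az,gx,gy,gz[,mx,my,mz][,qw,qx,qy,qz]`` and a
manifest carrying subject/session/test metadata, phase markers and the
declared units. Readers convert nothing silently: a manifest must declare
``m/s^2`` and ``deg/s`` and anything else is rejected.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    SITES,
    DataError,
    FormatError,
    ImuRecording,
    SensorSet,
    TrialMeta,
)

log = logging.getLogger(__name__)

_REQUIRED_COLS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_MAG_COLS = ["mx", "my", "mz"]
_QUAT_COLS = ["qw", "qx", "qy", "qz"]
_ACC_UNITS = "m/s^2"
_GYRO_UNITS = "deg/s"


def _read_sensor_csv(path: Path, rate_hz: float) -> ImuRecording:
    df = pd.read_csv(path)
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    t = df["t"].to_numpy(float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    mag = df[_MAG_COLS].to_numpy(float) if all(c in df.columns for c in _MAG_COLS) else None
    quat = df[_QUAT_COLS].to_numpy(float) if all(c in df.columns for c in _QUAT_COLS) else None
    return ImuRecording(
        time=t,
        acc=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        mag=mag,
        quat=quat,
        rate_hz=rate_hz,
    )


def read_trial(manifest_path) -> SensorSet:
    """Load a trial from its JSON manifest.

    Missing optional sensors are simply absent from the returned set; a
    warning is logged for each site named in neither the manifest nor on
    disk.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        man = json.load(fh)
    units = man.get("units", {})
    if units.get("acc") != _ACC_UNITS or units.get("gyro") != _GYRO_UNITS:
        raise FormatError(
            f"{manifest_path}: units block must declare acc={_ACC_UNITS!r} "
            f"gyro={_GYRO_UNITS!r}, got {units!r}"
        )
    rate_hz = float(man["rate_hz"])
    cond = man.get("condition", {})
    meta = TrialMeta(
        subject_id=man["subject_id"],
        cohort=man["cohort"],
        session=man["session"],
        days_elapsed=float(man["days_elapsed"]),
        test=man["test"],
        vision=cond.get("vision", "EO"),
        leg=cond.get("leg", "none"),
        heel=cond.get("heel", "none"),
        trial_index=int(man.get("trial_index", 1)),
        phases={k: tuple(v) for k, v in man.get("phases", {}).items()},
    )
    sensors = {}
    for site in SITES:
        fname = man.get("sensors", {}).get(site)
        if fname is None:
            log.warning("%s: no %s sensor in manifest", manifest_path.name, site)
            continue
        sensors[site] = _read_sensor_csv(manifest_path.parent / fname, rate_hz)
    if not sensors:
        raise FormatError(f"{manifest_path}: manifest names no sensor files")
    return SensorSet(sensors=sensors, meta=meta)


def write_trial(sset: SensorSet, out_dir, stem: str | None = None) -> Path:
    """Write one trial as per-sensor CSVs plus a manifest; returns manifest path.

    Floats are written with 17 significant digits so that a read/write
    round trip reproduces every channel bit-for-bit (well inside 1e-9).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = sset.meta
    if stem is None:
        stem = f"{m.subject_id}_{m.session}_{m.test}_{m.condition_label().replace('|', '-')}_t{m.trial_index}"
    sensor_files = {}
    for site, rec in sset.sensors.items():
        cols = {"t": rec.time}
        for name, arr in (("a", rec.acc), ("g", rec.gyro)):
            for i, ax in enumerate("xyz"):
                cols[f"{name}{ax}"] = arr[:, i]
        if rec.mag is not None:
            for i, ax in enumerate("xyz"):
                cols[f"m{ax}"] = rec.mag[:, i]
        if rec.quat is not None:
            for i, ax in enumerate("wxyz"):
                cols[f"q{ax}"] = rec.quat[:, i]
        fname = f"{stem}_{site}.csv"
        pd.DataFrame(cols).to_csv(out_dir / fname, index=False,
                                  float_format="%.17g")
        sensor_files[site] = fname
    man = {
        "subject_id": m.subject_id,
        "cohort": m.cohort,
        "session": m.session,
        "days_elapsed": m.days_elapsed,
        "test": m.test,
        "condition": {"vision": m.vision, "leg": m.leg, "heel": m.heel},
        "trial_index": m.trial_index,
        "rate_hz": sset.rate_hz,
        "phases": {k: list(v) for k, v in m.phases.items()},
        "sensors": sensor_files,
        "units": {"acc": _ACC_UNITS, "gyro": _GYRO_UNITS},
    }
    manifest_path = out_dir / f"{stem}.json"
    with open(manifest_path, "w") as fh:
        json.dump(man, fh, indent=1)
    return manifest_path


def synchronize(sset: SensorSet) -> SensorSet:
    """Crop all recordings to their common window and resample onto one grid.

    The grid starts at the latest per-sensor start time, steps at the
    declared rate and spans floor(overlap * rate) + 1 samples. Channels are
    linearly interpolated; quaternion rows are re-normalized afterwards.
    Idempotent: already-aligned sets come back unchanged.
    """
    rate = sset.rate_hz
    t0 = max(rec.time[0] for rec in sset.sensors.values())
    t1 = min(rec.time[-1] for rec in sset.sensors.values())
    if t1 < t0:
        raise DataError("recordings have no temporal overlap")
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    out = {}
    for site, rec in sset.sensors.items():
        if rec.n_samples == n and abs(rec.time[0] - t0) < 1e-12 \
                and np.all(np.abs(rec.time - grid) < 1e-9):
            out[site] = rec
            continue

        def interp(arr):
            return np.column_stack(
                [np.interp(grid, rec.time, arr[:, i]) for i in range(arr.shape[1])]
            )

        quat = None
        if rec.quat is not None:
            quat = interp(rec.quat)
            quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        out[site] = ImuRecording(
            time=grid,
            acc=interp(rec.acc),
            gyro=interp(rec.gyro),
            mag=interp(rec.mag) if rec.mag is not None else None,
            quat=quat,
            rate_hz=rate,
        )
    return SensorSet(sensors=out, meta=sset.meta)


def write_metric_rows(rows, path) -> Path:
    """Write a list of MetricRow to CSV with the standard header."""
    from .datamodel import MetricRow

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    MetricRow.to_frame(rows).to_csv(path, index=False)
    return path


def read_metric_rows(path) -> pd.DataFrame:
    return pd.read_csv(path)
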