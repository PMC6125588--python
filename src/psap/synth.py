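"""Forward-model generator of synthetic sensor trials with known truth.

Every generator builds ground-truth kinematics first (segment positions
in the world frame, ankle angular velocity trains, letter trajectories),
then renders them through a rigid-body sensor model: world acceleration
is obtained by numerically double-differentiating the truth positions,
gravity is added, the result is rotated into a (randomly or explicitly)
tilted sensor frame, and white sensor noise is appended. Because the
free acceleration handed to the analysis pipeline is by construction the
second numerical derivative of the truth position, forward generation
and inverse (double-integration) analysis are mutually consistent.

Default signal parameters emulate the tandem-walk / prone-to-stand /
leg-writing protocols: 100 Hz sampling, ~1.25 s stride period with
~200 deg/s sagittal swing peaks, centimetre-scale upper-body sway, and
MTw-class output noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .datamodel import G, ConfigError, ImuRecording, SensorSet, TrialMeta
from .stats import LongitudinalTable

RATE_HZ_DEFAULT = 100.0

#: default per-sample sensor noise SD: MTw-class output noise after the
#: device's internal strapdown filtering.
NOISE_ACC_SD = 0.003   # m/s^2
NOISE_GYRO_SD = 0.1    # deg/s

#: how strongly each upper-body site expresses the commanded trunk sway
SITE_SWAY_SCALE = {"head": 1.2, "trunk": 1.0, "pelvis": 0.5}

# Letter strokes for S, N, O, W in a unit (width, height) box, written in
# the (ML, vertical) plane; fixed so generated writing trials are
# reproducible. The path splines through all letters in sequence.
LETTER_POINTS = {
    "S": [(0.8, 0.95), (0.4, 1.0), (0.1, 0.85), (0.35, 0.6), (0.65, 0.45),
          (0.85, 0.2), (0.5, 0.0), (0.1, 0.1)],
    "N": [(0.0, 0.0), (0.0, 0.5), (0.0, 1.0), (0.4, 0.5), (0.8, 0.0),
          (0.8, 0.5), (0.8, 1.0)],
    "O": [(0.9, 0.5), (0.7, 0.93), (0.3, 0.93), (0.1, 0.5), (0.3, 0.07),
          (0.7, 0.07), (0.9, 0.5)],
    "W": [(0.0, 1.0), (0.2, 0.0), (0.45, 0.7), (0.7, 0.0), (0.9, 1.0)],
}


@dataclass
class TandemGenParams:
    n_strides: int = 12
    stride_period_s: float = 1.25
    timing_jitter_frac: float = 0.0
    amplitude_jitter_frac: float = 0.0
    peak_gyro_dps: float = 200.0
    sway_amp_cm: float = 3.0
    sway_freq_hz: float = 0.5
    tilt_deg: dict = field(default_factory=dict)  # site -> fixed tilt, deg
    noise_acc: float = NOISE_ACC_SD
    noise_gyro: float = NOISE_GYRO_SD
    lead_foot: str = "right"
    rate_hz: float = RATE_HZ_DEFAULT
    seed: int = 0


@dataclass
class SyntheticTruth:
    seed: int
    toe_off_times_s: dict = field(default_factory=dict)   # foot -> times
    true_sway_ml: dict = field(default_factory=dict)      # site -> cm curve
    time: np.ndarray | None = None
    letter_path: np.ndarray | None = None                 # (n, 2) metres
    sway_sd_cm: float | None = None
    tremor_amp_mss: float | None = None
    cohort_trend: float | None = None


def _tilt_rotation_deg(angle_deg: float, rng: np.random.Generator) -> Rotation:
    """Fixed sensor tilt: rotation about a random horizontal axis (no yaw)."""
    if angle_deg == 0:
        return Rotation.identity()
    phi = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(phi), np.sin(phi), 0.0])
    return Rotation.from_rotvec(axis * np.deg2rad(angle_deg))


def _second_derivative(pos: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(np.gradient(pos, dt, axis=0), dt, axis=0)


def _render_site(time: np.ndarray, pos_m: np.ndarray, gyro_world_dps: np.ndarray,
                 tilt: Rotation, noise_acc: float, noise_gyro: float,
                 rng: np.random.Generator, rate_hz: float) -> ImuRecording:
    """World kinematics -> sensor readings (specific force + angular rate)."""
    dt = 1.0 / rate_hz
    acc_world = _second_derivative(pos_m, dt)
    acc_world[:, 2] += G
    acc_sensor = tilt.inv().apply(acc_world)
    gyro_sensor = tilt.inv().apply(gyro_world_dps)
    if noise_acc > 0:
        acc_sensor = acc_sensor + rng.normal(0, noise_acc, acc_sensor.shape)
    if noise_gyro > 0:
        gyro_sensor = gyro_sensor + rng.normal(0, noise_gyro, gyro_sensor.shape)
    return ImuRecording(time=time, acc=acc_sensor, gyro=gyro_sensor,
                        rate_hz=rate_hz)


def _raised_cosine_train(time: np.ndarray, centers: np.ndarray,
                         amps: np.ndarray, width: float) -> np.ndarray:
    """Sum of raised-cosine pulses of given centers/amplitudes/width."""
    out = np.zeros_like(time)
    for c, a in zip(centers, amps):
        m = (time >= c - width / 2) & (time <= c + width / 2)
        out[m] += a * 0.5 * (1 + np.cos(2 * np.pi * (time[m] - c) / width))
    return out


def _envelope(time: np.ndarray, start: float, end: float,
              ramp: float = 1.0) -> np.ndarray:
    """Smooth 0->1->0 window over [start, end] with cosine ramps."""
    env = np.zeros_like(time)
    inside = (time >= start) & (time <= end)
    env[inside] = 1.0
    up = inside & (time < start + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (time[up] - start) / ramp))
    down = inside & (time > end - ramp)
    env[down] = 0.5 * (1 - np.cos(np.pi * (end - time[down]) / ramp))
    return env


def gen_tandem(params: TandemGenParams, meta_kw: dict | None = None
               ) -> tuple[SensorSet, SyntheticTruth]:
    """Synthetic tandem-walk trial: stride trains + upper-body ML sway."""
    if params.n_strides < 3:
        raise ConfigError("need at least 3 strides")
    if params.lead_foot not in ("left", "right"):
        raise ConfigError(f"bad lead foot {params.lead_foot!r}")
    rng = np.random.default_rng(params.seed)
    rate = params.rate_hz
    period = params.stride_period_s
    calib_end = 3.0
    walk_start = calib_end
    walk_dur = params.n_strides * period + 1.5
    walk_end = walk_start + walk_dur
    total = walk_end + 2.0
    n = int(round(total * rate)) + 1
    time = np.arange(n) / rate
    truth = SyntheticTruth(seed=params.seed, time=time)

    # --- ankle sagittal angular-velocity trains (alternating feet) ---
    feet = (params.lead_foot, "left" if params.lead_foot == "right" else "right")
    width = 0.5 * period
    gyro = {}
    for k, foot in enumerate(feet):
        base = walk_start + 0.75 + k * period / 2 + np.arange(params.n_strides) * period
        centers = base + rng.normal(0, params.timing_jitter_frac * period,
                                    params.n_strides)
        centers = np.sort(centers)
        amps = params.peak_gyro_dps * (
            1 + rng.normal(0, params.amplitude_jitter_frac, params.n_strides))
        truth.toe_off_times_s[foot] = centers
        g = np.zeros((n, 3))
        g[:, 1] = _raised_cosine_train(time, centers, amps, width)  # ML = sagittal
        gyro[foot] = g

    # --- upper-body ML sway (position, metres) ---
    env = _envelope(time, walk_start, walk_end, ramp=1.0)
    sway = np.sin(2 * np.pi * params.sway_freq_hz * (time - walk_start)) * env
    pos = {}
    for site, scale in SITE_SWAY_SCALE.items():
        p = np.zeros((n, 3))
        p[:, 1] = scale * params.sway_amp_cm / 100.0 * sway
        pos[site] = p
        truth.true_sway_ml[site] = p[:, 1] * 100.0
    zeros = np.zeros((n, 3))

    sensors = {}
    for site in ("head", "trunk", "pelvis"):
        tilt = _tilt_rotation_deg(params.tilt_deg.get(site, 0.0), rng)
        sensors[site] = _render_site(time, pos[site], zeros, tilt,
                                     params.noise_acc, params.noise_gyro,
                                     rng, rate)
    for foot in ("left", "right"):
        site = f"{foot}_ankle"
        tilt = _tilt_rotation_deg(params.tilt_deg.get(site, 0.0), rng)
        sensors[site] = _render_site(time, zeros, gyro[foot], tilt,
                                     params.noise_acc, params.noise_gyro,
                                     rng, rate)

    kw = dict(subject_id="sim", cohort="crew", session="pre", days_elapsed=0.0,
              test="tandem", vision="EO", trial_index=1)
    kw.update(meta_kw or {})
    kw["phases"] = {"calib": (0.5, 2.5), "walk": (walk_start, walk_end)}
    return SensorSet(sensors=sensors, meta=TrialMeta(**kw)), truth


def gen_prone_to_stand(sway_sd_cm: float = 0.5, duration_s: float = 60.0,
                       seed: int = 0, prone_s: float = 10.0,
                       noise_acc: float = NOISE_ACC_SD,
                       noise_gyro: float = NOISE_GYRO_SD,
                       tilt_deg: dict | None = None,
                       rate_hz: float = RATE_HZ_DEFAULT,
                       meta_kw: dict | None = None
                       ) -> tuple[SensorSet, SyntheticTruth]:
    """Synthetic prone-then-quiet-stand trial.

    The quiet-stand ML/AP position is a 0.3 Hz low-passed Gaussian walk
    with the requested stationary SD; a smooth anterior excursion renders
    the stand-up transition. The prone phase doubles as the static
    calibration window. ``prone_s`` defaults to a shortened prone phase —
    enough for calibration without simulating the full rest period.
    """
    if duration_s < 10:
        raise ConfigError("stand duration must be >= 10 s")
    if sway_sd_cm < 0:
        raise ConfigError("sway SD must be >= 0")
    rng = np.random.default_rng(seed)
    trans = 2.0
    settle_s = 5.0  # stabilization before the scored quiet stand begins
    stand_start = prone_s + trans + settle_s
    total = stand_start + duration_s + 1.0
    n = int(round(total * rate_hz)) + 1
    time = np.arange(n) / rate_hz
    truth = SyntheticTruth(seed=seed, time=time, sway_sd_cm=sway_sd_cm)

    def sway_track() -> np.ndarray:
        w = rng.normal(0, 1, n)
        sos = signal.butter(4, 0.3, btype="low", fs=rate_hz, output="sos")
        x = signal.sosfiltfilt(sos, w)
        sd = x.std()
        if sd > 0 and sway_sd_cm > 0:
            x = x / sd * (sway_sd_cm / 100.0)
        else:
            x = np.zeros(n)
        return x * _envelope(time, stand_start, total - 0.5, ramp=1.0)

    ml, ap = sway_track(), sway_track()
    # stand-up: smooth 5 cm anterior excursion during the transition
    bump = np.zeros(n)
    m = (time >= prone_s) & (time <= prone_s + trans)
    bump[m] = 0.05 * 0.5 * (1 - np.cos(2 * np.pi * (time[m] - prone_s) / trans))
    ap_full = ap + bump

    tilt_deg = tilt_deg or {}
    sensors = {}
    zeros = np.zeros((n, 3))
    for site, scale in SITE_SWAY_SCALE.items():
        p = np.zeros((n, 3))
        p[:, 1] = scale * ml
        p[:, 0] = scale * ap_full
        truth.true_sway_ml[site] = p[:, 1] * 100.0
        tilt = _tilt_rotation_deg(tilt_deg.get(site, 0.0), rng)
        sensors[site] = _render_site(time, p, zeros, tilt, noise_acc,
                                     noise_gyro, rng, rate_hz)

    kw = dict(subject_id="sim", cohort="crew", session="pre", days_elapsed=0.0,
              test="prone_to_stand", vision="EO", trial_index=1)
    kw.update(meta_kw or {})
    kw["phases"] = {"calib": (1.0, prone_s - 1.0), "prone": (0.0, prone_s),
                    "stand": (stand_start, stand_start + duration_s)}
    return SensorSet(sensors=sensors, meta=TrialMeta(**kw)), truth


def letter_path_points(height_m: float = 0.15) -> np.ndarray:
    """Control points of the S-N-O-W trace in the (ML, vertical) plane, m."""
    pts = []
    offset = 0.0
    for letter in "SNOW":
        for (u, v) in LETTER_POINTS[letter]:
            pts.append((offset + u, v))
        offset += 1.4
    pts = np.asarray(pts, float)
    pts -= pts.mean(axis=0)
    return pts * height_m


def gen_snow(tremor_amp_mss: float = 0.0, seed: int = 0, leg: str = "right",
             heel: str = "air", write_s: float = 16.0,
             noise_acc: float = NOISE_ACC_SD, noise_gyro: float = NOISE_GYRO_SD,
             tilt_deg: dict | None = None, rate_hz: float = RATE_HZ_DEFAULT,
             meta_kw: dict | None = None) -> tuple[SensorSet, SyntheticTruth]:
    """Synthetic leg letter-writing trial.

    The foot traces a spline through fixed S-N-O-W control points at
    constant speed (cosine speed ramps at both ends); tremor is 4–8 Hz
    band-limited noise of the requested RMS added to the writing-plane
    acceleration during the write phase only.
    """
    if tremor_amp_mss < 0:
        raise ConfigError("tremor amplitude must be >= 0")
    if leg not in ("left", "right"):
        raise ConfigError(f"bad leg {leg!r}")
    rng = np.random.default_rng(seed)
    calib_end = 3.0
    write_start, write_end = calib_end, calib_end + write_s
    total = write_end + 1.0
    n = int(round(total * rate_hz)) + 1
    time = np.arange(n) / rate_hz

    pts = letter_path_points()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(arclen, pts, axis=0)

    # constant traversal speed with 0.5 s cosine ramps
    speed = _envelope(time, write_start, write_end, ramp=0.5)
    s = np.cumsum(speed) / rate_hz
    s = s / s[-1] * arclen[-1]
    path = spline(s)  # (n, 2): (ML, vertical)
    pos = np.zeros((n, 3))
    pos[:, 1] = path[:, 0]
    pos[:, 2] = path[:, 1]

    tilt_deg = tilt_deg or {}
    zeros = np.zeros((n, 3))
    site = f"{leg}_ankle"
    tilt = _tilt_rotation_deg(tilt_deg.get(site, 0.0), rng)
    rec = _render_site(time, pos, zeros, tilt, noise_acc, noise_gyro, rng,
                       rate_hz)
    if tremor_amp_mss > 0:
        sos = signal.butter(4, (4.0, 8.0), btype="bandpass", fs=rate_hz,
                            output="sos")
        env = _envelope(time, write_start, write_end, ramp=0.5)
        tremor = signal.sosfiltfilt(sos, rng.normal(0, 1, (n, 3)), axis=0)
        tremor *= tremor_amp_mss / np.sqrt(np.mean(tremor ** 2))
        rec = ImuRecording(time=time, acc=rec.acc + tilt.inv().apply(tremor * env[:, None]),
                           gyro=rec.gyro, rate_hz=rate_hz)

    sensors = {site: rec}
    for other in ("pelvis", f"{'left' if leg == 'right' else 'right'}_ankle"):
        t2 = _tilt_rotation_deg(tilt_deg.get(other, 0.0), rng)
        sensors[other] = _render_site(time, np.zeros((n, 3)), zeros, t2,
                                      noise_acc, noise_gyro, rng, rate_hz)

    truth = SyntheticTruth(seed=seed, time=time, letter_path=path,
                           tremor_amp_mss=tremor_amp_mss)
    kw = dict(subject_id="sim", cohort="crew", session="pre", days_elapsed=0.0,
              test="snow", vision="EO", leg=leg, heel=heel, trial_index=1)
    kw.update(meta_kw or {})
    kw["phases"] = {"calib": (0.5, 2.5), "write": (write_start, write_end)}
    return SensorSet(sensors=sensors, meta=TrialMeta(**kw)), truth


CREW_SESSION_DAYS = {"pre": 0.0, "in_first": 2.0, "in_last": 13.0, "post": 14.0}
CONTROL_SESSION_DAYS = {"pre": 0.0, "in_first": 3.0, "in_last": 6.0, "post": 8.0}


def gen_cohort(n_subjects: int, sessions: int = 4, trend_sd_units: float = 0.0,
               noise_sd: float = 1.0, seed: int = 0, n_controls: int = 0,
               trials_per_cell: int = 3, baseline_sd: float | None = None,
               variable: str = "SyntheticMetric", condition: str = "EC",
               test: str = "tandem") -> LongitudinalTable:
    """Cohort-level metric table with a known injected trend.

    Each cell is the mean of ``trials_per_cell`` trial-level draws, the
    way the study averages its repeated trials; ``noise_sd`` is the
    trial-level measurement SD. The trend is a linear drift over the full
    stay expressed in units of ``noise_sd`` (crew only; controls get zero
    trend). ``baseline_sd`` is the between-subject spread of the metric
    baseline (default 0.2·noise_sd — small, matching the pooled-correlation
    analysis's assumption that subjects share a common metric scale).
    """
    if n_subjects < 2:
        raise ConfigError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    if baseline_sd is None:
        baseline_sd = 0.2 * noise_sd
    from .datamodel import SESSIONS

    rows = []
    groups = [("crew", n_subjects), ("control", n_controls)]
    for cohort, n_sub in groups:
        days_map = CREW_SESSION_DAYS if cohort == "crew" else CONTROL_SESSION_DAYS
        day_max = max(days_map.values())
        slope = trend_sd_units * noise_sd / day_max if cohort == "crew" else 0.0
        for i in range(n_sub):
            sid = f"{'crew' if cohort == 'crew' else 'ctrl'}{i + 1:02d}"
            baseline = 10.0 + rng.normal(0, baseline_sd)
            for sess in SESSIONS[:sessions]:
                day = days_map[sess]
                vals = baseline + slope * day + rng.normal(0, noise_sd,
                                                           trials_per_cell)
                rows.append({
                    "subject_id": sid, "cohort": cohort, "session": sess,
                    "days_elapsed": day, "test": test, "condition": condition,
                    "variable": variable, "value": float(np.mean(vals)),
                    "units": "a.u.",
                })
    return LongitudinalTable(pd.DataFrame(rows))


def simulate_mission(n_crew: int = 10, n_controls: int = 5, seed: int = 0,
                     tandem_trials: int = 2, snow_tremor_gain: float = 0.4,
                     n_strides: int = 10):
    """Yield SensorSets for a full two-cohort study, all three tests.

    Crew deteriorate with days in the habitat (growing sway amplitude,
    stride jitter and writing tremor); controls stay at baseline. Controls
    perform the tandem walk only, matching the study protocol. Trials are
    generated lazily so a batch run streams rather than holds the whole
    mission in memory.
    """
    rng = np.random.default_rng(seed)
    groups = [("crew", n_crew), ("control", n_controls)]
    from .datamodel import SESSIONS

    for cohort, n_sub in groups:
        days_map = CREW_SESSION_DAYS if cohort == "crew" else CONTROL_SESSION_DAYS
        for i in range(n_sub):
            sid = f"{'crew' if cohort == 'crew' else 'ctrl'}{i + 1:02d}"
            sub_sway = 2.0 * (1 + 0.15 * rng.standard_normal())
            sub_tilt = {s: rng.uniform(2, 15) for s in
                        ("head", "trunk", "pelvis", "left_ankle", "right_ankle")}
            for sess in SESSIONS:
                day = days_map[sess]
                sev = day / 14.0 if cohort == "crew" else 0.0
                meta_base = dict(subject_id=sid, cohort=cohort, session=sess,
                                 days_elapsed=day)
                for vision in ("EO", "EC"):
                    vis_gain = 1.5 if vision == "EC" else 1.0
                    for k in range(tandem_trials):
                        params = TandemGenParams(
                            n_strides=n_strides,
                            timing_jitter_frac=0.02 + 0.08 * sev * vis_gain,
                            amplitude_jitter_frac=0.02 + 0.05 * sev * vis_gain,
                            sway_amp_cm=sub_sway * (1 + 0.6 * sev * vis_gain),
                            tilt_deg=sub_tilt,
                            seed=int(rng.integers(2 ** 31)),
                        )
                        yield gen_tandem(params, meta_kw=dict(
                            **meta_base, vision=vision, trial_index=k + 1))[0]
                if cohort != "crew":
                    continue
                for vision in ("EO", "EC"):
                    vis_gain = 1.5 if vision == "EC" else 1.0
                    yield gen_prone_to_stand(
                        sway_sd_cm=0.3 * (1 + 1.0 * sev * vis_gain),
                        duration_s=30.0, tilt_deg=sub_tilt,
                        seed=int(rng.integers(2 ** 31)),
                        meta_kw=dict(**meta_base, vision=vision,
                                     trial_index=1))[0]
                for heel in ("air", "ground"):
                    yield gen_snow(
                        tremor_amp_mss=snow_tremor_gain * sev,
                        leg="right", heel=heel, tilt_deg=sub_tilt,
                        seed=int(rng.integers(2 ** 31)),
                        meta_kw=dict(**meta_base, vision="EO",
                                     trial_index=1))[0]
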