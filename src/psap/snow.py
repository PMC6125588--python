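"""Lower-limb coordination metrics for the leg letter-writing (SNOW) test.

Two complementary measures are computed from the active ankle's free
acceleration while the subject writes the letters S, N, O, W with the
leg:

* Jerk cost — the squared magnitude of jerk (the time derivative of
  acceleration) integrated over the writing phase, split into a
  horizontal (X/Y plane) and a vertical (Z) component. Smooth, well
  coordinated movement minimizes jerk; stumbling and corrective
  sub-movements inflate it. Acceleration is low-passed at 5 Hz before
  differentiation so sensor noise is not amplified into the derivative.

* Sample entropy (SampEn) — −ln A/B, where B counts template pairs of
  length m within Chebyshev tolerance r and A the same for length m+1.
  A regular, repetitive trace yields low entropy; disordered motion
  raises it. Field-standard parameters m=2, r=0.2·SD.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import ConfigError, DataError, MetricRow, SensorSet
from .orientation import FrameAlignment, remove_gravity
from .balance import FilterSpec, butter_filter


@dataclass
class SnowParams:
    lowpass_hz: float | None = 5.0
    m: int = 2
    r_frac: float = 0.2
    duration_normalize: bool = False  # report mean-square jerk instead of integrated


@dataclass
class SnowResult:
    leg: str
    heel: str
    vision: str
    jerk_horizontal: float   # (m/s^3)^2 * s
    jerk_vertical: float
    sampen_horizontal: float  # nats
    sampen_vertical: float
    params: SnowParams


def jerk_cost(acc_free: np.ndarray, rate_hz: float,
              phase: tuple[float, float], time: np.ndarray | None = None,
              lowpass_hz: float | None = 5.0,
              duration_normalize: bool = False) -> tuple[float, float]:
    """(horizontal, vertical) integrated squared jerk over a phase.

    ``acc_free``: (n, 3) gravity-free acceleration, m/s^2. Pass
    ``lowpass_hz=None`` to differentiate the raw signal (analytic checks).
    """
    acc = np.asarray(acc_free, float)
    start, end = phase
    if end - start < 1.0:
        raise DataError("writing phase must span at least 1 s")
    dt = 1.0 / rate_hz
    if time is None:
        time = np.arange(len(acc)) * dt
    if lowpass_hz is not None:
        spec = FilterSpec(order=4, cutoff_hz=lowpass_hz, kind="lowpass")
        acc = np.column_stack([butter_filter(acc[:, i], spec, rate_hz)
                               for i in range(3)])
    jerk = np.gradient(acc, dt, axis=0)
    m = (time >= start) & (time < end)
    if m.sum() < 3:
        raise DataError("writing phase contains too few samples")
    t = time[m]
    horiz = float(np.trapezoid(jerk[m, 0] ** 2 + jerk[m, 1] ** 2, t))
    vert = float(np.trapezoid(jerk[m, 2] ** 2, t))
    if duration_normalize:
        dur = t[-1] - t[0]
        horiz /= dur
        vert /= dur
    return horiz, vert


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_frac: float = 0.2) -> float:
    """Sample entropy of a series (nats).

    ``r`` is the absolute Chebyshev tolerance; when omitted it defaults to
    ``r_frac`` times the series SD, which makes the result invariant to
    affine rescaling of the input. Counts unordered template pairs i<j
    over the first n−m templates for both lengths (the standard
    Richman–Moorman convention). Returns ``inf`` when no (m+1)-length pair
    matches; raises when no m-length pair matches (entropy undefined).
    """
    x = np.asarray(x, float)
    n = len(x)
    if n <= m + 1:
        raise DataError(f"series of length {n} too short for m={m}")
    if r is None:
        sd = float(x.std(ddof=0))
        if sd == 0:
            sd = 1.0  # constant series: any positive tolerance matches everything
        r = r_frac * sd
    if r <= 0:
        raise ConfigError("tolerance r must be positive")
    n_templates = n - m  # templates of length m+1 (and the first n-m of length m)

    def pair_count(length: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, length)[:n_templates]
        # Chebyshev distances between all template pairs, O(n^2) memory-lean loop
        count = 0
        for i in range(n_templates - 1):
            d = np.max(np.abs(templ[i + 1:] - templ[i]), axis=1)
            count += int(np.sum(d <= r))
        return count

    b = pair_count(m)
    if b == 0:
        raise DataError("no matching m-length templates; entropy undefined (B=0)")
    a = pair_count(m + 1)
    if a == 0:
        return math.inf
    return -math.log(a / b)


def snow_trial_metrics(sset: SensorSet, align: FrameAlignment,
                       params: SnowParams = SnowParams()) -> SnowResult:
    """All four SNOW metrics from the active ankle over the write phase."""
    meta = sset.meta
    if meta.leg not in ("left", "right"):
        raise ConfigError(f"SNOW trial needs an active leg, got {meta.leg!r}")
    site = f"{meta.leg}_ankle"
    if site not in sset:
        raise ConfigError(f"active ankle sensor {site} not present")
    phase = meta.phase("write")
    rec = sset[site]
    free = remove_gravity(rec, align, site)
    jh, jv = jerk_cost(free.acc_free, rec.rate_hz, phase, time=rec.time,
                       lowpass_hz=params.lowpass_hz,
                       duration_normalize=params.duration_normalize)
    m = (rec.time >= phase[0]) & (rec.time < phase[1])
    acc = free.acc_free[m]
    horiz = np.hypot(acc[:, 0], acc[:, 1])
    vert = acc[:, 2]
    se_h = sample_entropy(horiz, m=params.m, r_frac=params.r_frac)
    se_v = sample_entropy(vert, m=params.m, r_frac=params.r_frac)
    return SnowResult(
        leg=meta.leg, heel=meta.heel, vision=meta.vision,
        jerk_horizontal=jh, jerk_vertical=jv,
        sampen_horizontal=se_h, sampen_vertical=se_v,
        params=params,
    )


def snow_metric_rows(sset: SensorSet, align: FrameAlignment,
                     params: SnowParams = SnowParams()) -> list[MetricRow]:
    """SNOW result as four MetricRows."""
    res = snow_trial_metrics(sset, align, params)
    meta = sset.meta
    jerk_units = "(m/s^3)^2*s" if not params.duration_normalize else "(m/s^3)^2"
    rows = []
    for var, val, units in (
        ("JerkHorizontal", res.jerk_horizontal, jerk_units),
        ("JerkVertical", res.jerk_vertical, jerk_units),
        ("SampEnHorizontal", res.sampen_horizontal, "nats"),
        ("SampEnVertical", res.sampen_vertical, "nats"),
    ):
        rows.append(MetricRow(
            subject_id=meta.subject_id, cohort=meta.cohort,
            session=meta.session, days_elapsed=meta.days_elapsed,
            test=meta.test, condition=meta.condition_label(),
            variable=var, value=val, units=units,
        ))
    return rows
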