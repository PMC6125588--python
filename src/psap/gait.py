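"""Stride segmentation and DTW gait regularity from ankle angular velocity.

During tandem walking the shank rotates rapidly in the sagittal plane at
the start of each swing; the sagittal (ML-axis) angular velocity shows one
dominant peak per stride. Toe-off events are detected as prominent peaks
of the 6 Hz low-passed signal, strides are the intervals between
consecutive events, and a stride template is the pointwise mean of the
strides after resampling each to a common length. Regularity is scored as
the dynamic-time-warping (DTW) distance of every stride to the template;
the mean, SD and range of those distances summarize how repeatable the
gait is — the less coordinated the gait, the larger all three.

DTW is implemented directly: dynamic programming over the local cost
|a_i − b_j| with steps (1,1), (1,0), (0,1) and full boundary conditions.
The returned distance is the accumulated cost divided by the warping-path
length, so it keeps the units of the input signal (deg/s).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ConfigError, DataError, SensorSet
from .orientation import FrameAlignment, aligned_gyro
from .balance import AXIS_ML, FilterSpec, butter_filter


@dataclass
class GaitParams:
    lowpass_hz: float = 6.0
    prom_frac: float = 0.3      # prominence fraction of (max - median)
    prom_abs: float = 20.0      # absolute prominence floor, deg/s
    refractory_s: float = 0.6   # minimum event separation (tandem gait is slow)
    template_length: int = 100
    normalize_dtw: bool = True
    exclude_boundary_strides: bool = False


@dataclass
class StrideSet:
    foot: str
    events: np.ndarray              # toe-off sample indices
    strides: list = field(default_factory=list)   # raw segments, deg/s
    template: np.ndarray | None = None            # length-L mean stride
    template_sd: np.ndarray | None = None
    distances: np.ndarray | None = None           # per-stride DTW distance


@dataclass
class RegularityResult:
    foot: str
    mean: float
    sd: float
    range: float
    n_strides: int


def detect_toe_off(gyro_sagittal: np.ndarray, rate_hz: float,
                   params: GaitParams = GaitParams()) -> np.ndarray:
    """Toe-off sample indices: prominent peaks of the low-passed signal.

    Returns an empty array when nothing crosses the prominence floor; the
    caller decides whether that is an error.
    """
    from scipy.signal import find_peaks

    x = np.asarray(gyro_sagittal, float)
    if len(x) < 2 * rate_hz:
        raise DataError("need at least 2 s of signal for event detection")
    spec = FilterSpec(order=4, cutoff_hz=params.lowpass_hz, kind="lowpass")
    xf = butter_filter(x, spec, rate_hz)
    prom = max(params.prom_abs,
               params.prom_frac * float(xf.max() - np.median(xf)))
    peaks, _ = find_peaks(xf, prominence=prom,
                          distance=max(1, round(params.refractory_s * rate_hz)))
    return peaks.astype(int)


def segment_strides(series: np.ndarray, events: np.ndarray) -> list:
    """Stride k = samples [event_k, event_{k+1}); needs >= 2 events."""
    series = np.asarray(series, float)
    events = np.asarray(events, int)
    if len(events) < 2:
        raise DataError(f"insufficient strides: {len(events)} event(s), need >= 2")
    return [series[events[k]:events[k + 1]] for k in range(len(events) - 1)]


def resample_stride(stride: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of one stride onto ``length`` evenly spaced points."""
    stride = np.asarray(stride, float)
    if len(stride) < 2:
        raise DataError("stride too short to resample")
    src = np.linspace(0.0, 1.0, len(stride))
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, stride)


def build_template(strides, length: int = 100):
    """Pointwise mean (and SD band) of strides resampled to a common length."""
    if len(strides) < 3:
        raise DataError(f"need >= 3 strides to build a template, got {len(strides)}")
    rs = np.vstack([resample_stride(s, length) for s in strides])
    return rs.mean(axis=0), rs.std(axis=0, ddof=0)


def dtw_alignment(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Accumulated DTW cost and warping-path length.

    Steps (1,1), (1,0), (0,1); ties in the DP minimization prefer the
    diagonal, then the step along ``a``, so the backtrace is deterministic.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise DataError("DTW inputs must be nonempty")
    cost = np.abs(a[:, None] - b[None, :])
    D = np.empty((n, m))
    P = np.empty((n, m), dtype=np.int64)  # path length (nodes) to each cell
    D[0, 0] = cost[0, 0]
    P[0, 0] = 1
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + cost[0, j]
        P[0, j] = j + 1
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + cost[i, 0]
        P[i, 0] = i + 1
        row_c = cost[i]
        prev = D[i - 1]
        prevP = P[i - 1]
        cur = D[i]
        curP = P[i]
        for j in range(1, m):
            diag = prev[j - 1]
            up = prev[j]
            left = cur[j - 1]
            best = diag
            bestP = prevP[j - 1]
            if up < best:
                best = up
                bestP = prevP[j]
            if left < best:
                best = left
                bestP = curP[j - 1]
            cur[j] = best + row_c[j]
            curP[j] = bestP + 1
    return float(D[n - 1, m - 1]), int(P[n - 1, m - 1])


def dtw_distance(a, b, normalize: bool = True) -> float:
    """DTW distance; divided by warping-path length when ``normalize``."""
    cost, path_len = dtw_alignment(a, b)
    return cost / path_len if normalize else cost


def stride_set(gyro_sagittal: np.ndarray, rate_hz: float, foot: str,
               params: GaitParams = GaitParams()) -> StrideSet:
    """Full per-foot pipeline: detect, segment, template, score."""
    events = detect_toe_off(gyro_sagittal, rate_hz, params)
    if len(events) < 4:
        raise DataError(
            f"{foot} foot: {max(0, len(events) - 1)} stride(s) detected, need >= 3")
    strides = segment_strides(np.asarray(gyro_sagittal, float), events)
    if params.exclude_boundary_strides and len(strides) > 4:
        strides = strides[1:-1]
    L = params.template_length
    template, template_sd = build_template(strides, L)
    rs = [resample_stride(s, L) for s in strides]
    distances = np.array([dtw_distance(s, template, params.normalize_dtw)
                          for s in rs])
    return StrideSet(foot=foot, events=events, strides=strides,
                     template=template, template_sd=template_sd,
                     distances=distances)


def regularity(sset: SensorSet, align: FrameAlignment, foot: str,
               params: GaitParams = GaitParams()) -> RegularityResult:
    """Gait-regularity summary (mean/SD/range of DTW distances) for one foot."""
    site = f"{foot}_ankle"
    if site not in sset:
        raise ConfigError(f"{site} sensor not present")
    walk = sset.meta.phase("walk")
    rec = sset[site].slice_seconds(*walk)
    sagittal = aligned_gyro(rec, align, site)[:, AXIS_ML]
    ss = stride_set(sagittal, rec.rate_hz, foot, params)
    d = ss.distances
    return RegularityResult(
        foot=foot,
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)),
        range=float(d.max() - d.min()),
        n_strides=len(d),
    )
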