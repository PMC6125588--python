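"""Quiet-stance postural sway from upper-body displacement.

The horizontal-plane (ML, AP) displacement cloud during the quiet-stand
phase is summarized by the sensor-traced path length, the total sway area
(convex-hull area of the cloud — the standard posturography choice; a 95%
prediction-ellipse area is available as an alternative) and the maximum
ML and AP excursions (peak-to-peak range per axis).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ConfigError, DataError, MetricRow, SensorSet, UPPER_BODY_SITES
from .balance import AXIS_AP, AXIS_ML, BalanceConfig, DisplacementCurve, ml_displacement


@dataclass
class SwayResult:
    site: str
    path_length: float      # cm
    total_area: float       # cm^2
    max_ml_excursion: float  # cm
    max_ap_excursion: float  # cm


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area of a 2-D point cloud; 0 for degenerate clouds."""
    from scipy.spatial import ConvexHull, QhullError

    pts = np.asarray(points, float)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # in 2-D, .volume is the area
    except QhullError:
        return 0.0  # collinear or coincident points enclose no area


def ellipse95_area(points: np.ndarray) -> float:
    """Area of the 95% prediction ellipse of a 2-D Gaussian fit, cm^2."""
    from scipy.stats import chi2

    pts = np.asarray(points, float)
    if len(pts) < 3:
        return 0.0
    cov = np.cov(pts.T)
    det = float(np.linalg.det(cov))
    if det <= 0:
        return 0.0
    return float(np.pi * chi2.ppf(0.95, df=2) * np.sqrt(det))


def sway_metrics(ml: DisplacementCurve, ap: DisplacementCurve,
                 phase: tuple[float, float], site: str = "",
                 area_method: str = "hull") -> SwayResult:
    """Path / area / excursion summary of the (ML, AP) trace over a phase."""
    start, end = phase
    if end - start < 5.0:
        raise DataError(f"stand phase of {end - start:.1f} s is too short (< 5 s)")
    if len(ml.time) != len(ap.time):
        raise DataError("ML and AP curves must share one timeline")
    m = (ml.time >= start) & (ml.time < end)
    x = ml.disp[m]
    y = ap.disp[m]
    pts = np.column_stack([x, y])
    path = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    if area_method == "hull":
        area = hull_area(pts)
    elif area_method == "ellipse95":
        area = ellipse95_area(pts)
    else:
        raise ConfigError(f"unknown area method {area_method!r}")
    return SwayResult(
        site=site,
        path_length=path,
        total_area=area,
        max_ml_excursion=float(np.ptp(x)) if len(x) else 0.0,
        max_ap_excursion=float(np.ptp(y)) if len(y) else 0.0,
    )


def prone_to_stand_metrics(
    sset: SensorSet,
    align,
    config: BalanceConfig = BalanceConfig(),
    area_method: str = "hull",
) -> list[MetricRow]:
    """Sway rows per upper-body site over the quiet-stand phase.

    Only the quiet stand is scored; the prone phase and the stand-up
    transition are excluded via the phase markers, and an edge trim keeps
    the transition's filter transient out of the scored window.
    """
    meta = sset.meta
    stand = meta.phase("stand")
    phase = (stand[0] + config.edge_trim_s, stand[1] - config.edge_trim_s)
    rows = []
    for site in UPPER_BODY_SITES:
        if site not in sset:
            continue
        ml = ml_displacement(sset, align, site, config, axis=AXIS_ML)
        ap = ml_displacement(sset, align, site, config, axis=AXIS_AP)
        res = sway_metrics(ml, ap, phase, site=site, area_method=area_method)
        cap = site.capitalize()
        for var, val, units in (
            (f"SwayPath_{cap}", res.path_length, "cm"),
            (f"SwayArea_{cap}", res.total_area, "cm^2"),
            (f"MaxExcursionML_{cap}", res.max_ml_excursion, "cm"),
            (f"MaxExcursionAP_{cap}", res.max_ap_excursion, "cm"),
        ):
            rows.append(MetricRow(
                subject_id=meta.subject_id, cohort=meta.cohort,
                session=meta.session, days_elapsed=meta.days_elapsed,
                test=meta.test, condition=meta.condition_label(),
                variable=var, value=val, units=units,
            ))
    if not rows:
        raise DataError("no upper-body sensor present")
    return rows
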