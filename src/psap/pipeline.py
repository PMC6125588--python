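"""Trial -> metrics -> cohort-table -> statistics orchestration.

``run_trial`` dispatches one trial to the metric module matching its
test. ``aggregate`` averages repeated trials into one value per
(subject, session, condition, variable) cell — eyes-open and eyes-closed
rows are never pooled. ``run_study`` chains everything and writes the
study outputs (metrics, cohort table, statistics report, provenance).
Per-trial failures are logged and skipped; one bad trial never aborts a
batch.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import ConfigError, MetricRow, SensorSet
from .io import read_trial, synchronize
from .orientation import build_alignment
from .balance import BalanceConfig, tandem_balance_metrics
from .gait import GaitParams, regularity
from .snow import SnowParams, snow_metric_rows
from .sway import prone_to_stand_metrics
from .stats import ALPHA_DEFAULT, LongitudinalTable, analyze_cohort, reports_to_frame

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "input_dir", "out_dir", "alpha", "time_axis", "gg_correction",
    "area_method", "balance", "gait", "snow", "calib_phase",
    "use_device_quaternions",
}


@dataclass
class RunConfig:
    input_dir: str | None = None
    out_dir: str = "psap_out"
    alpha: float = ALPHA_DEFAULT
    time_axis: str = "days"          # days | session
    gg_correction: bool = False
    area_method: str = "hull"
    calib_phase: str = "calib"
    use_device_quaternions: bool = True
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    gait: GaitParams = field(default_factory=GaitParams)
    snow: SnowParams = field(default_factory=SnowParams)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for key, sub in (("balance", BalanceConfig), ("gait", GaitParams),
                         ("snow", SnowParams)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_trial(trial, config: RunConfig = RunConfig()) -> list[MetricRow]:
    """Compute all metric rows for one trial (manifest path or SensorSet)."""
    if not isinstance(trial, SensorSet):
        trial = read_trial(trial)
    sset = synchronize(trial)
    meta = sset.meta
    calib = meta.phase(config.calib_phase)
    align = build_alignment(sset, calib,
                            use_device_quaternions=config.use_device_quaternions)
    rows: list[MetricRow] = []
    if meta.test == "tandem":
        rows += tandem_balance_metrics(sset, align, config.balance)
        for foot in ("right", "left"):
            if f"{foot}_ankle" not in sset:
                continue
            res = regularity(sset, align, foot, config.gait)
            cap = foot.capitalize()
            for suffix, value in (("Mean", res.mean), ("SD", res.sd),
                                  ("Range", res.range)):
                rows.append(MetricRow(
                    subject_id=meta.subject_id, cohort=meta.cohort,
                    session=meta.session, days_elapsed=meta.days_elapsed,
                    test=meta.test, condition=meta.condition_label(),
                    variable=f"GaitRegularity_{cap}_{suffix}",
                    value=value, units="deg/s",
                ))
    elif meta.test == "prone_to_stand":
        rows += prone_to_stand_metrics(sset, align, config.balance,
                                       config.area_method)
    elif meta.test == "snow":
        rows += snow_metric_rows(sset, align, config.snow)
    else:  # pragma: no cover - TrialMeta already validates
        raise ConfigError(f"unknown test {meta.test!r}")
    log.info("trial %s/%s/%s t%d: %d metric rows", meta.subject_id,
             meta.session, meta.test, meta.trial_index, len(rows))
    return rows


def run_batch(trials, config: RunConfig = RunConfig()) -> list[MetricRow]:
    """Run many trials with per-trial isolation; failures are logged."""
    rows: list[MetricRow] = []
    n_failed = 0
    for trial in trials:
        try:
            rows += run_trial(trial, config)
        except Exception as exc:
            n_failed += 1
            name = trial if not isinstance(trial, SensorSet) else (
                f"{trial.meta.subject_id}/{trial.meta.session}/"
                f"{trial.meta.test} t{trial.meta.trial_index}")
            log.warning("skipping trial %s: %s", name, exc)
    if n_failed:
        log.warning("%d trial(s) skipped", n_failed)
    return rows


def aggregate(rows: list[MetricRow]) -> LongitudinalTable:
    """Mean over repeated trials per (subject, session, condition, variable)."""
    if not rows:
        raise ConfigError("no metric rows to aggregate")
    df = MetricRow.to_frame(rows)
    keys = ["subject_id", "cohort", "session", "days_elapsed", "test",
            "condition", "variable", "units"]
    agg = df.groupby(keys, sort=True, as_index=False)["value"].mean()
    return LongitudinalTable(agg)


def run_study(config: RunConfig, trials=None) -> dict:
    """Full study: trials -> metrics -> cohort table -> statistics -> files.

    ``trials`` may be an iterable of SensorSets; otherwise every
    ``*.json`` manifest under ``config.input_dir`` is processed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if trials is None:
        if config.input_dir is None:
            raise ConfigError("no input: set input_dir or pass trials")
        trials = sorted(p for p in Path(config.input_dir).glob("**/*.json")
                        if p.name not in ("truth.json", "provenance.json"))
        if not trials:
            raise ConfigError(f"no trial manifests under {config.input_dir}")
    rows = run_batch(trials, config)
    if not rows:
        raise ConfigError("no trial produced any metrics")
    metrics = MetricRow.to_frame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    table = aggregate(rows)
    table.data.to_csv(out / "cohort_table.csv", index=False)
    reports = analyze_cohort(table, alpha=config.alpha,
                             time_axis=config.time_axis,
                             gg_correction=config.gg_correction)
    stats_df = reports_to_frame(reports)
    stats_df.to_csv(out / "stats_report.csv", index=False)
    stats_df.to_json(out / "stats_report.json", orient="records", indent=1)
    with open(out / "provenance.json", "w") as fh:
        json.dump({"config": config.to_dict(), "version": __version__,
                   "n_trials": int(metrics.groupby(
                       ["subject_id", "session", "test", "condition"]).ngroups),
                   "n_metric_rows": len(metrics)}, fh, indent=1, default=str)
    return {"metrics": metrics, "table": table.data, "stats": stats_df}
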