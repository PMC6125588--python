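"""Longitudinal statistics over the metric table.

For every (cohort, test, condition, variable) cell set the analysis
follows the study design: Pearson correlation of the metric against time
in the environment (days elapsed, pooled over subjects and sessions);
where the correlation is significant, a one-way within-subject
(repeated-measures) ANOVA across the four sessions; where the ANOVA is
significant, Fisher's Least Significant Difference pairwise contrasts —
uncorrected pairwise t-tests using the ANOVA error term, which is what
LSD means.

The RM-ANOVA is the textbook sums-of-squares decomposition
SS_total = SS_subject + SS_session + SS_error on complete cases, with
F = MS_session / MS_error on (k−1, (k−1)(n−1)) degrees of freedom and no
sphericity correction by default (Greenhouse–Geisser behind a flag).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import SESSIONS, DataError

ALPHA_DEFAULT = 0.05


class InsufficientData(DataError):
    """Too few subjects/sessions for the requested analysis."""


@dataclass
class LongitudinalTable:
    """Subject × session × variable table; one value per cell.

    ``data`` columns: subject_id, cohort, session, days_elapsed, test,
    condition, variable, value, units. At most one row per
    (subject, session, condition, variable).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.data.duplicated(
            subset=["subject_id", "session", "condition", "variable"])
        if dup.any():
            raise DataError("more than one value per (subject, session, "
                            "condition, variable) cell; aggregate trials first")

    def cells(self):
        """Iterate (cohort, test, condition, variable) groups."""
        for key, grp in self.data.groupby(
                ["cohort", "test", "condition", "variable"], sort=True):
            yield key, grp


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    ms_error: float
    session_means: dict
    n_subjects: int
    ss: dict = field(default_factory=dict)
    gg_epsilon: float | None = None


@dataclass
class StatReport:
    variable: str
    condition: str
    cohort: str = ""
    test: str = ""
    r: float = np.nan
    r_p: float = np.nan
    n_obs: int = 0
    anova_F: float = np.nan
    anova_df: tuple = (np.nan, np.nan)
    anova_p: float = np.nan
    n_subjects: int = 0
    posthoc: list = field(default_factory=list)  # (session_i, session_j, p)
    note: str = ""


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise DataError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientData(f"need n >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _complete_case_matrix(grp: pd.DataFrame) -> tuple[np.ndarray, list]:
    """(n_subjects, k_sessions) value matrix for subjects with all sessions."""
    pivot = grp.pivot_table(index="subject_id", columns="session",
                            values="value", aggfunc="mean")
    present = [s for s in SESSIONS if s in pivot.columns]
    pivot = pivot[present].dropna()
    return pivot.to_numpy(float), list(pivot.index)


def rm_anova(table: LongitudinalTable, variable: str, condition: str,
             gg_correction: bool = False) -> AnovaResult:
    """One-way within-subject ANOVA of a variable across sessions."""
    grp = table.data[(table.data["variable"] == variable)
                     & (table.data["condition"] == condition)]
    mat, subjects = _complete_case_matrix(grp)
    n, k = mat.shape if mat.ndim == 2 else (0, 0)
    if n < 3 or k < 2:
        raise InsufficientData(
            f"{variable}/{condition}: {n} complete subject(s) across {k} "
            "session(s); need >= 3 subjects and >= 2 sessions")
    grand = mat.mean()
    subj_means = mat.mean(axis=1)
    sess_means = mat.mean(axis=0)
    ss_total = float(((mat - grand) ** 2).sum())
    ss_subject = float(k * ((subj_means - grand) ** 2).sum())
    ss_session = float(n * ((sess_means - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_session
    df_session = k - 1
    df_error = (k - 1) * (n - 1)
    ms_session = ss_session / df_session
    ms_error = ss_error / df_error
    F = ms_session / ms_error if ms_error > 0 else (0.0 if ms_session == 0 else np.inf)
    eps = None
    d1, d2 = df_session, df_error
    if gg_correction:
        eps = _gg_epsilon(mat)
        d1, d2 = d1 * eps, d2 * eps
    p = float(sps.f.sf(F, d1, d2)) if np.isfinite(F) else 0.0
    present = [s for s in SESSIONS if s in grp["session"].unique()]
    return AnovaResult(
        F=float(F), df=(df_session, df_error), p=p, ms_error=ms_error,
        session_means={s: float(m) for s, m in zip(present, sess_means)},
        n_subjects=n,
        ss={"total": ss_total, "subject": ss_subject,
            "session": ss_session, "error": ss_error},
        gg_epsilon=eps,
    )


def _gg_epsilon(mat: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the session covariance matrix."""
    k = mat.shape[1]
    S = np.cov(mat.T, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S ** 2) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k ** 2 * mean_all ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def lsd_posthoc(anova: AnovaResult, alpha: float = ALPHA_DEFAULT) -> list:
    """All pairwise session contrasts with the LSD (uncorrected) t-test."""
    if anova.p > alpha:
        raise DataError(
            f"post hoc requested but ANOVA p={anova.p:.3g} > alpha={alpha}")
    n = anova.n_subjects
    df_error = anova.df[1]
    out = []
    sessions = list(anova.session_means)
    for si, sj in itertools.combinations(sessions, 2):
        diff = anova.session_means[si] - anova.session_means[sj]
        se = np.sqrt(2.0 * anova.ms_error / n)
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), df_error))
        out.append((si, sj, p))
    return out


def analyze_cohort(table: LongitudinalTable, alpha: float = ALPHA_DEFAULT,
                   time_axis: str = "days",
                   gg_correction: bool = False) -> list[StatReport]:
    """Run the gated analysis chain for every (cohort, test, condition, variable).

    ``time_axis``: ``"days"`` correlates against days_elapsed, ``"session"``
    against the ordinal session index.
    """
    if time_axis not in ("days", "session"):
        raise DataError(f"unknown time axis {time_axis!r}")
    reports = []
    for (cohort, test, condition, variable), grp in table.cells():
        rep = StatReport(variable=variable, condition=condition,
                         cohort=cohort, test=test)
        if time_axis == "days":
            x = grp["days_elapsed"].to_numpy(float)
        else:
            x = np.array([SESSIONS.index(s) + 1 for s in grp["session"]], float)
        y = grp["value"].to_numpy(float)
        finite = np.isfinite(y)
        x, y = x[finite], y[finite]
        rep.n_obs = len(y)
        try:
            rep.r, rep.r_p = pearson(x, y)
        except DataError as exc:
            rep.note = f"correlation skipped: {exc}"
            reports.append(rep)
            continue
        if rep.r_p <= alpha:
            sub = LongitudinalTable(grp[finite])
            try:
                an = rm_anova(sub, variable, condition, gg_correction)
            except InsufficientData as exc:
                rep.note = f"ANOVA skipped: {exc}"
                reports.append(rep)
                continue
            rep.anova_F, rep.anova_df, rep.anova_p = an.F, an.df, an.p
            rep.n_subjects = an.n_subjects
            if an.p <= alpha:
                rep.posthoc = lsd_posthoc(an, alpha)
        reports.append(rep)
    return reports


def reports_to_frame(reports: list[StatReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "cohort": r.cohort, "test": r.test, "condition": r.condition,
            "variable": r.variable, "n_obs": r.n_obs, "r": r.r, "r_p": r.r_p,
            "anova_F": r.anova_F, "anova_df1": r.anova_df[0],
            "anova_df2": r.anova_df[1], "anova_p": r.anova_p,
            "n_subjects": r.n_subjects,
            "significant_pairs": ";".join(
                f"{a}-{b}" for a, b, p in r.posthoc if p <= ALPHA_DEFAULT),
            "note": r.note,
        })
    return pd.DataFrame(rows)
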