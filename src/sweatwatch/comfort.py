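"""Thermal-comfort statistics over multi-subject sweat-rate sessions.

Subjects report thermal sensation on the nine-point scale from 'very cold'
(−4) to 'very hot' (+4) while their sweat rate is measured repeatedly at
each status. The discrimination question is whether adjacent statuses
differ in sweat rate and how much subjects vary among themselves:

* per-status summaries: mean and sample (n−1) standard deviation of
  subject-level mean sweat rates across subjects, plus the coefficient of
  variation CV = 100·sd/mean;
* adjacent-status differences: for each subject, differences of per-status
  means between consecutive statuses actually present (later minus
  earlier), summarized per subject and pooled across subjects;
* a nearest-mean status classifier.

All standard deviations use the n−1 sample convention throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError
from .synth import THERMAL_LABELS


@dataclass(frozen=True)
class ThermalStatus:
    """One point on the nine-point thermal sensation scale."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in THERMAL_LABELS:
            raise DomainError(f"status code {self.code} outside -4..+4")

    @property
    def label(self) -> str:
        return THERMAL_LABELS[self.code]


@dataclass
class SubjectSession:
    """One subject's sweat-rate readings grouped by thermal status."""

    subject_id: str
    records: list[tuple[ThermalStatus, list[float]]]

    def __post_init__(self) -> None:
        codes = [s.code for s, _ in self.records]
        if len(codes) != len(set(codes)):
            raise DomainError("statuses within a session must be distinct")
        for status, readings in self.records:
            if not readings:
                raise DomainError(f"status {status.code} has no readings")
            if any(r <= 0 for r in readings):
                raise DomainError("sweat-rate readings must be positive")

    def status_means(self) -> dict[int, float]:
        """Per-status mean of this subject's readings, keyed by code."""
        return {s.code: float(np.mean(r)) for s, r in self.records}


@dataclass
class StatusSummary:
    """Across-subject summary of sweat rate at one thermal status."""

    status: ThermalStatus
    mean_gm2h: float
    sd_gm2h: float | None  # None when < 2 subjects
    cv_pct: float | None  # 100·sd/mean
    n_subjects: int


def _sample_sd(values: list[float]) -> float:
    return float(np.std(values, ddof=1))


def summaries_from_moments(
    moments: dict[int, tuple[float, float]], n_subjects: int = 3
) -> list[StatusSummary]:
    """Build status summaries directly from (mean, sd) pairs.

    Useful when only the summary moments of a study are available, e.g.
    when re-deriving coefficients of variation from tabulated figures.
    """
    out = []
    for code in sorted(moments):
        mean, sd = moments[code]
        cv = 100.0 * sd / mean if mean > 0 else None
        out.append(
            StatusSummary(
                status=ThermalStatus(code),
                mean_gm2h=mean,
                sd_gm2h=sd,
                cv_pct=cv,
                n_subjects=n_subjects,
            )
        )
    return out


def mean_cv(summaries: list[StatusSummary]) -> float:
    """Unweighted average of the per-status CVs (percent)."""
    cvs = [s.cv_pct for s in summaries if s.cv_pct is not None]
    if not cvs:
        raise InsufficientDataError("no summary has a defined CV")
    return float(np.mean(cvs))


def status_statistics(
    sessions: list[SubjectSession],
) -> tuple[list[StatusSummary], float]:
    """Across-subject per-status summaries and the mean inter-subject CV.

    For every status present in any session, the subject-level mean sweat
    rates are aggregated across subjects (mean, n−1 sd, CV). Statuses with
    a single subject get ``sd = cv = None`` and do not enter the mean CV.
    """
    if not sessions:
        raise InsufficientDataError("no sessions")
    by_status: dict[int, list[float]] = {}
    for session in sessions:
        for code, mean in session.status_means().items():
            by_status.setdefault(code, []).append(mean)
    summaries = []
    for code in sorted(by_status):
        values = by_status[code]
        mean = float(np.mean(values))
        if len(values) >= 2:
            sd = _sample_sd(values)
            cv = 100.0 * sd / mean if mean > 0 else None
        else:
            sd = cv = None
        summaries.append(
            StatusSummary(
                status=ThermalStatus(code),
                mean_gm2h=mean,
                sd_gm2h=sd,
                cv_pct=cv,
                n_subjects=len(values),
            )
        )
    return summaries, mean_cv(summaries)


def difference_stats(diffs: list[float]) -> tuple[float, float]:
    """Mean and n−1 sd of a list of adjacent-status differences.

    With a single difference the sd is NaN.
    """
    if not diffs:
        raise InsufficientDataError("no differences")
    mean = float(np.mean(diffs))
    sd = _sample_sd(diffs) if len(diffs) >= 2 else float("nan")
    return mean, sd


def adjacent_differences(
    session: SubjectSession,
) -> tuple[list[float], float, float]:
    """Sweat-rate steps between consecutive thermal statuses of one subject.

    Differences are taken between per-status mean sweat rates of statuses
    actually present, ordered by code, signed later minus earlier. Returns
    ``(diffs, mean, sd)`` with the n−1 sample sd.
    """
    means = session.status_means()
    if len(means) < 2:
        raise InsufficientDataError("session needs >= 2 statuses")
    codes = sorted(means)
    diffs = [means[b] - means[a] for a, b in zip(codes, codes[1:])]
    mean, sd = difference_stats(diffs)
    return diffs, mean, sd


def pooled_differences(
    sessions: list[SubjectSession],
) -> tuple[float, float, int]:
    """Adjacent-status differences pooled over all subjects.

    Concatenates every subject's difference list and returns
    ``(mean, n−1 sd, n differences)``.
    """
    all_diffs: list[float] = []
    for session in sessions:
        try:
            diffs, _, _ = adjacent_differences(session)
        except InsufficientDataError:
            continue
        all_diffs.extend(diffs)
    if not all_diffs:
        raise InsufficientDataError("no session has computable differences")
    mean, sd = difference_stats(all_diffs)
    return mean, sd, len(all_diffs)


def classify_status(
    sweat_rate: float, summaries: list[StatusSummary]
) -> ThermalStatus:
    """Assign a sweat rate to the status with the nearest mean.

    Ties are broken toward the lower status code.
    """
    if not summaries:
        raise DomainError("no summaries to classify against")
    best: StatusSummary | None = None
    best_dist = math.inf
    for summary in sorted(summaries, key=lambda s: s.status.code):
        dist = abs(sweat_rate - summary.mean_gm2h)
        if dist < best_dist:
            best, best_dist = summary, dist
    assert best is not None
    return best.status
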