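"""Session reports, persistent history, and before/after phase comparison.

Reproduces the monitoring GUI's data-logging functions in machine-readable
form: for each wearing session it aggregates the day's total sitting
duration, the number of posture changes, and the reminder counts; sessions
are appended to a JSON-lines history store; and paired before/after
intervention phases are compared with a paired-sample t-test on per-subject
posture-change counts.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .engine import POSTURE_CHANGE, SEDENTARY, ReminderEvent
from .postures import Posture
from .simulate import ClassificationStream


@dataclass
class SessionReport:
    """Logged aggregates for one wearing session."""

    date: str
    total_sitting_s: int
    posture_changes: int
    sedentary_reminders: int
    posture_reminders: int

    def __post_init__(self) -> None:
        for name in ("total_sitting_s", "posture_changes",
                     "sedentary_reminders", "posture_reminders"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return dict(vars(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SessionReport":
        return cls(**{k: d[k] for k in (
            "date", "total_sitting_s", "posture_changes",
            "sedentary_reminders", "posture_reminders")})


@dataclass
class PhaseComparison:
    """Paired-sample t-test result over per-subject counts."""

    before: list[int]
    after: list[int]
    t_statistic: float
    p_value: float | None
    n_subjects: int
    degenerate: bool = False


def _debounced_runs(labels: Sequence[Posture], debounce: int) -> list[Posture]:
    """Run labels surviving jitter suppression, with same-label merges."""
    runs = [(label, len(list(g))) for label, g in itertools.groupby(labels)]
    kept = [label for label, length in runs if length >= debounce]
    merged: list[Posture] = []
    for label in kept:
        if not merged or merged[-1] != label:
            merged.append(label)
    return merged


def summarize_session(
    stream: ClassificationStream,
    events: Sequence[ReminderEvent],
    debounce: int = 3,
    date: str | None = None,
) -> SessionReport:
    """Aggregate one session's stream and reminder events into a report.

    ``total_sitting_s`` counts non-stance ticks. ``posture_changes`` counts
    transitions between distinct labels after suppressing runs shorter than
    ``debounce`` seconds (classifier jitter is not a real posture change).
    """
    if not stream.ticks:
        raise ValueError("empty stream")
    t_lo, t_hi = stream.ticks[0][0], stream.ticks[-1][0]
    for e in events:
        if not t_lo <= e.t <= t_hi:
            raise ValueError(
                f"event at t={e.t} outside the stream's range [{t_lo}, {t_hi}]"
            )
    labels = stream.labels()
    runs = _debounced_runs(labels, debounce)
    return SessionReport(
        date=date or _dt.date.today().isoformat(),
        total_sitting_s=sum(1 for p in labels if p is not Posture.STANCE),
        posture_changes=max(0, len(runs) - 1),
        sedentary_reminders=sum(1 for e in events if e.kind == SEDENTARY),
        posture_reminders=sum(1 for e in events if e.kind == POSTURE_CHANGE),
    )


def compare_phases(
    before: Sequence[float], after: Sequence[float]
) -> PhaseComparison:
    """Paired-sample t-test on per-subject counts from two phases.

    The statistic is computed on the differences ``before − after``, so the
    t value is negative when counts rise in the second phase. A zero-variance
    difference vector is flagged degenerate (t is 0 when the vectors are
    identical, otherwise undefined) and carries no p-value.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length paired vectors")
    n = len(before)
    if n < 2:
        raise ValueError("need at least two paired subjects")
    diffs = before - after
    if np.std(diffs, ddof=1) == 0:
        t = 0.0 if diffs.mean() == 0 else float("nan")
        return PhaseComparison(list(before), list(after), t, None, n, True)
    res = stats.ttest_rel(before, after)
    return PhaseComparison(
        list(before), list(after), float(res.statistic), float(res.pvalue), n
    )


def persist_history(report: SessionReport, store: str | Path) -> None:
    """Append one session report to a JSON-lines history store."""
    with open(store, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(report.to_dict()) + "\n")


def load_history(store: str | Path) -> list[SessionReport]:
    """Load all session reports from a history store, oldest first.

    Corrupt lines are skipped with a single warning reporting their count.
    """
    path = Path(store)
    if not path.exists():
        return []
    reports: list[SessionReport] = []
    skipped = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        try:
            reports.append(SessionReport.from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} corrupt history record(s)", stacklevel=2)
    return reports


def render_session_table(report: SessionReport) -> str:
    """Plain-text rendering of the GUI's logged fields."""
    minutes, seconds = divmod(report.total_sitting_s, 60)
    return "\n".join(
        [
            f"Date                  {report.date}",
            f"Total sitting time    {minutes} min {seconds} s",
            f"Posture changes       {report.posture_changes}",
            f"Posture reminders     {report.posture_reminders}",
            f"Sedentary reminders   {report.sedentary_reminders}",
        ]
    )
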