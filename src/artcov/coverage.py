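"""Day-level prescription coverage under carryover, duplicate and censoring rules.

The adherence measure is *prescription coverage*: a day is covered when the
patient holds enough prescribed supply of their full regimen for that day.
Coverage is driven by a single scalar balance of "days of supply remaining":

* at each prescription issue, if the agent set is unchanged from the
  previous prescription, the remaining balance (capped at
  ``carryover_cap_days``, clinic policy 30) is credited and the new
  duration added; a regimen change forfeits the balance;
* between issues the balance decays one day per calendar day (never below
  zero); a day is covered iff the balance is positive on that day.

Re-recorded balances of long prescriptions (e.g. a 3-month record entered
3 months after a 6-month prescription) are duplicates, not new supply, and
are dropped before any balance arithmetic.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import PatientRecord, PrescriptionRecord

PRE_PROGRAM = "pre_program"
DURING_PROGRAM = "during_program"


class ContractError(ValueError):
    """Raised when an operation's precondition is violated."""


@dataclass(frozen=True)
class ObservationWindow:
    """The closed date interval over which one patient contributes days."""

    patient_id: str
    start: dt.date
    end: dt.date
    has_pre_program_time: bool

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class DailyCoverageSeries:
    """Per-patient day-indexed coverage with active-prescription annotations.

    ``frame`` has one row per day of the observation window with columns
    ``date`` (datetime64), ``covered`` (bool), ``period`` (pre_program /
    during_program), ``active_rx_duration_days`` (int), ``active_line``
    (first/second) and ``active_fdc`` (bool).  Annotations describe the most
    recently issued prescription, carried forward across uncovered gaps.
    """

    patient_id: str
    frame: pd.DataFrame

    @property
    def n_days(self) -> int:
        return len(self.frame)

    @property
    def n_covered(self) -> int:
        return int(self.frame["covered"].sum())


def _check_sorted(prescriptions: Sequence[PrescriptionRecord]) -> None:
    for a, b in zip(prescriptions, prescriptions[1:]):
        if b.issue_date < a.issue_date:
            raise ContractError("prescriptions must be sorted by issue_date")


def deduplicate(prescriptions: Sequence[PrescriptionRecord]):
    """Split one patient's chronological prescriptions into (kept, dropped).

    A record is dropped iff an earlier *kept* record has an identical agent
    set and fully contains its coverage interval — the signature of a
    re-recorded remaining balance rather than a new prescription.
    """
    _check_sorted(prescriptions)
    kept: list = []
    dropped: list = []
    for rec in prescriptions:
        duplicate = any(
            earlier.agents == rec.agents
            and rec.issue_date >= earlier.issue_date
            and rec.end_date <= earlier.end_date
            for earlier in kept
        )
        (dropped if duplicate else kept).append(rec)
    return kept, dropped


def determine_window(
    patient: PatientRecord,
    prescriptions: Sequence[PrescriptionRecord],
    config: StudyConfig,
) -> ObservationWindow | None:
    """Observation window for one patient, or ``None`` if no observable time.

    Observation begins at the earlier of (a) the day after the end of the
    first recorded prescription and (b) the day of the second recorded
    prescription, but never before ``obs_start``; it ends at transfer-out
    or the end of pharmacy data, whichever is earlier.
    """
    _check_sorted(prescriptions)
    if not prescriptions:
        return None
    first = prescriptions[0]
    candidate = first.end_date + dt.timedelta(days=1)
    if len(prescriptions) > 1:
        candidate = min(candidate, prescriptions[1].issue_date)
    start = max(config.obs_start, candidate)
    end = config.data_end
    if patient.transfer_out_date is not None:
        end = min(end, patient.transfer_out_date)
    if start > end:
        return None
    return ObservationWindow(
        patient_id=patient.patient_id,
        start=start,
        end=end,
        has_pre_program_time=start < config.program_start,
    )


def compute_coverage(
    prescriptions: Sequence[PrescriptionRecord],
    window: ObservationWindow,
    config: StudyConfig,
) -> DailyCoverageSeries:
    """Run the balance simulation and restrict the result to ``window``.

    Prescriptions issued before the window still inform the carryover
    balance; the returned series spans exactly the window's days.
    """
    if window is None:
        raise ContractError("window is None")
    _check_sorted(prescriptions)
    if not prescriptions:
        raise ContractError("cannot compute coverage without prescriptions")

    cap = config.carryover_cap_days
    balance = 0.0
    prev_issue: dt.date | None = None
    prev_agents = None
    avail: list = []  # days of supply available at each issue moment
    for rec in prescriptions:
        if prev_issue is not None:
            balance = max(0.0, balance - (rec.issue_date - prev_issue).days)
        if prev_agents is not None and rec.agents == prev_agents:
            balance = min(balance, cap) + rec.duration_days
        else:
            balance = float(rec.duration_days)
        avail.append(balance)
        prev_issue = rec.issue_date
        prev_agents = rec.agents

    origin = np.datetime64(config.data_start)
    start_off = (window.start - config.data_start).days
    end_off = (window.end - config.data_start).days
    n = end_off - start_off + 1

    covered = np.zeros(n, dtype=bool)
    issue_offs = np.array(
        [(r.issue_date - config.data_start).days for r in prescriptions], dtype=int
    )
    for j, rec in enumerate(prescriptions):
        seg_start = issue_offs[j]
        seg_end = seg_start + int(avail[j]) - 1
        if j + 1 < len(prescriptions):
            seg_end = min(seg_end, issue_offs[j + 1] - 1)
        lo = max(seg_start, start_off) - start_off
        hi = min(seg_end, end_off) - start_off
        if hi >= lo:
            covered[lo : hi + 1] = True

    day_offs = np.arange(start_off, end_off + 1)
    # most recently issued prescription at or before each day
    active_idx = np.searchsorted(issue_offs, day_offs, side="right") - 1
    if np.any(active_idx < 0):
        raise ContractError("window contains days before the first prescription")
    durations = np.array([r.duration_days for r in prescriptions])
    lines = np.array([r.line for r in prescriptions])
    fdcs = np.array([r.fdc for r in prescriptions])

    program_off = (config.program_start - config.data_start).days
    period = np.where(day_offs < program_off, PRE_PROGRAM, DURING_PROGRAM)

    frame = pd.DataFrame(
        {
            "date": origin + day_offs.astype("timedelta64[D]"),
            "covered": covered,
            "period": period,
            "active_rx_duration_days": durations[active_idx],
            "active_line": lines[active_idx],
            "active_fdc": fdcs[active_idx],
        }
    )
    return DailyCoverageSeries(patient_id=window.patient_id, frame=frame)


def coverage_proportion(
    series: DailyCoverageSeries, period: str | None = None
) -> float | None:
    """Covered-day proportion over the whole window or one period.

    Returns ``None`` when the requested period contributes no days.
    """
    frame = series.frame
    if period is not None:
        frame = frame[frame["period"] == period]
    if len(frame) == 0:
        return None
    return float(frame["covered"].mean())


def export_coverage(path, series_list: Sequence[DailyCoverageSeries]) -> None:
    """Optional per-patient coverage export (patient_id, date, covered, period)."""
    frames = []
    for s in series_list:
        f = s.frame[["date", "covered", "period"]].copy()
        f.insert(0, "patient_id", s.patient_id)
        f["covered"] = f["covered"].astype(int)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
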