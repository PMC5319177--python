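"""On-disk schemas and validated CSV input/output for the three clinic tables.

Tables are plain CSV with ISO-8601 dates and columns named exactly after the
record fields:

* ``patients.csv`` — one row per clinic patient (demographics, enrollment,
  phone-availability status, censoring dates).
* ``prescriptions.csv`` — one row per prescribing event; the antiretroviral
  agent set is serialized as ``"+"``-joined uppercase codes in sorted order
  (e.g. ``EFV+FTC+TDF``) so that writing is canonical and ``read(write(x))``
  round-trips byte-identically.
* ``events.csv`` — SMS program events (intro message, opt-out, delivery
  confirmations); descriptive only under intention-to-treat.

Every rejected row is reported with its file, 1-based data row number and a
reason; accepted + rejected always sum to the file's row count.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .config import StudyConfig

PATIENT_COLUMNS = [
    "patient_id",
    "enrollment_date",
    "birth_date",
    "gender",
    "art_start_date",
    "transfer_out_date",
    "phone_status",
    "phone_capture_date",
    "opt_out_date",
]
PRESCRIPTION_COLUMNS = [
    "patient_id",
    "issue_date",
    "duration_days",
    "agents",
    "line",
    "fdc",
]
EVENT_COLUMNS = [
    "patient_id",
    "intro_sms_date",
    "opt_out_date",
    "delivery_confirmed_count",
]

GENDERS = ("female", "male")
PHONE_STATUSES = ("available", "absent", "unknown")
LINES = ("first", "second")
MAX_DURATION_DAYS = 186


class SchemaError(ValueError):
    """Raised when a file cannot be accepted (bad header or invalid rows)."""


@dataclass(frozen=True)
class PatientRecord:
    """One clinic patient.

    ``birth_date`` and ``gender`` may be absent (sparse missing covariates,
    later mean-imputed); structural fields may not.
    """

    patient_id: str
    enrollment_date: dt.date
    art_start_date: dt.date
    phone_status: str
    birth_date: dt.date | None = None
    gender: str | None = None
    transfer_out_date: dt.date | None = None
    phone_capture_date: dt.date | None = None
    opt_out_date: dt.date | None = None

    def age_years_at(self, reference: dt.date) -> float | None:
        """Fractional age in years at ``reference`` (365.25-day years)."""
        if self.birth_date is None:
            return None
        return (reference - self.birth_date).days / 365.25


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensing/prescribing event.

    ``agents`` is an unordered set of uppercase drug codes; the ``fdc``
    (fixed-dose combination) flag is packaging metadata and does not enter
    agent-set equality.
    """

    patient_id: str
    issue_date: dt.date
    duration_days: int
    agents: frozenset
    line: str
    fdc: bool

    @property
    def end_date(self) -> dt.date:
        """Last day covered by this prescription alone (inclusive)."""
        return self.issue_date + dt.timedelta(days=self.duration_days - 1)


@dataclass(frozen=True)
class ProgramEvent:
    patient_id: str
    intro_sms_date: dt.date | None
    opt_out_date: dt.date | None
    delivery_confirmed_count: int


@dataclass(frozen=True)
class RowDiagnostic:
    """Why one data row was rejected."""

    table: str
    row: int  # 1-based index among data rows (header excluded)
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table} row {self.row}: {self.reason}"


@dataclass
class ReadResult:
    patients: list
    prescriptions: list
    events: list
    diagnostics: list
    n_rows: dict = field(default_factory=dict)


def _opt_date(raw: str, what: str):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return dt.date.fromisoformat(raw)
    except ValueError:
        raise ValueError(f"malformed date in {what}: {raw!r}")


def _req_date(raw: str, what: str) -> dt.date:
    value = _opt_date(raw, what)
    if value is None:
        raise ValueError(f"missing required date {what}")
    return value


def serialize_agents(agents: Iterable[str]) -> str:
    return "+".join(sorted(agents))


def parse_agents(raw: str) -> frozenset:
    codes = [c.strip().upper() for c in raw.split("+") if c.strip()]
    if not codes:
        raise ValueError("agents must contain at least one drug code")
    return frozenset(codes)


def _parse_patient_row(row: dict) -> PatientRecord:
    pid = row["patient_id"].strip()
    if not pid:
        raise ValueError("empty patient_id")
    gender = row["gender"].strip().lower() or None
    if gender is not None and gender not in GENDERS:
        raise ValueError(f"unknown gender code {gender!r}")
    phone_status = row["phone_status"].strip().lower()
    if phone_status not in PHONE_STATUSES:
        raise ValueError(f"unknown phone_status code {phone_status!r}")
    rec = PatientRecord(
        patient_id=pid,
        enrollment_date=_req_date(row["enrollment_date"], "enrollment_date"),
        birth_date=_opt_date(row["birth_date"], "birth_date"),
        gender=gender,
        art_start_date=_req_date(row["art_start_date"], "art_start_date"),
        transfer_out_date=_opt_date(row["transfer_out_date"], "transfer_out_date"),
        phone_status=phone_status,
        phone_capture_date=_opt_date(row["phone_capture_date"], "phone_capture_date"),
        opt_out_date=_opt_date(row["opt_out_date"], "opt_out_date"),
    )
    if rec.birth_date is not None and rec.art_start_date < rec.birth_date:
        raise ValueError("art_start_date before birth_date")
    if rec.transfer_out_date is not None and rec.transfer_out_date < rec.enrollment_date:
        raise ValueError("transfer_out_date before enrollment_date")
    if rec.phone_status == "available" and rec.phone_capture_date is None:
        raise ValueError("phone_status=available requires phone_capture_date")
    return rec


def _parse_prescription_row(row: dict) -> PrescriptionRecord:
    pid = row["patient_id"].strip()
    if not pid:
        raise ValueError("empty patient_id")
    try:
        duration = int(row["duration_days"])
    except ValueError:
        raise ValueError(f"malformed duration_days: {row['duration_days']!r}")
    if not 1 <= duration <= MAX_DURATION_DAYS:
        raise ValueError(f"duration_days {duration} outside [1, {MAX_DURATION_DAYS}]")
    line = row["line"].strip().lower()
    if line not in LINES:
        raise ValueError(f"unknown line code {line!r}")
    fdc_raw = row["fdc"].strip()
    if fdc_raw not in ("0", "1"):
        raise ValueError(f"fdc must be 0 or 1, got {fdc_raw!r}")
    return PrescriptionRecord(
        patient_id=pid,
        issue_date=_req_date(row["issue_date"], "issue_date"),
        duration_days=duration,
        agents=parse_agents(row["agents"]),
        line=line,
        fdc=fdc_raw == "1",
    )


def _parse_event_row(row: dict) -> ProgramEvent:
    pid = row["patient_id"].strip()
    if not pid:
        raise ValueError("empty patient_id")
    try:
        count = int(row["delivery_confirmed_count"])
    except ValueError:
        raise ValueError(
            f"malformed delivery_confirmed_count: {row['delivery_confirmed_count']!r}"
        )
    if count < 0:
        raise ValueError("delivery_confirmed_count must be >= 0")
    return ProgramEvent(
        patient_id=pid,
        intro_sms_date=_opt_date(row["intro_sms_date"], "intro_sms_date"),
        opt_out_date=_opt_date(row["opt_out_date"], "opt_out_date"),
        delivery_confirmed_count=count,
    )


def _read_csv(path, columns: Sequence[str], parse_row, table: str):
    records, diagnostics = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{table}: empty file {path}")
        if header != list(columns):
            raise SchemaError(
                f"{table}: header {header} does not match schema {list(columns)}"
            )
        n = 0
        for i, raw in enumerate(reader, start=1):
            n += 1
            if len(raw) != len(columns):
                diagnostics.append(
                    RowDiagnostic(table, i, f"expected {len(columns)} fields, got {len(raw)}")
                )
                continue
            row = dict(zip(columns, raw))
            try:
                records.append(parse_row(row))
            except ValueError as exc:
                diagnostics.append(RowDiagnostic(table, i, str(exc)))
    return records, diagnostics, n


def read_tables(
    patients_path,
    prescriptions_path,
    events_path=None,
    config: StudyConfig | None = None,
    on_error: str = "raise",
) -> ReadResult:
    """Parse and validate the clinic tables.

    Parameters
    ----------
    on_error : {"raise", "collect"}
        ``"raise"`` (default) raises :class:`SchemaError` listing every
        rejected row; ``"collect"`` returns them in ``result.diagnostics``.

    Returns
    -------
    ReadResult
        Accepted records per table plus row-level diagnostics; for every
        table ``len(accepted) + len(rejected) == n_rows[table]``.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    patients, diag_p, n_p = _read_csv(
        patients_path, PATIENT_COLUMNS, _parse_patient_row, "patients"
    )
    seen: dict = {}
    unique_patients = []
    for rec in patients:
        if rec.patient_id in seen:
            diag_p.append(
                RowDiagnostic("patients", -1, f"duplicate patient_id {rec.patient_id!r}")
            )
        else:
            seen[rec.patient_id] = rec
            unique_patients.append(rec)
    prescriptions, diag_rx, n_rx = _read_csv(
        prescriptions_path, PRESCRIPTION_COLUMNS, _parse_prescription_row, "prescriptions"
    )
    events, diag_ev, n_ev = [], [], 0
    if events_path is not None:
        events, diag_ev, n_ev = _read_csv(
            events_path, EVENT_COLUMNS, _parse_event_row, "events"
        )
    diagnostics = diag_p + diag_rx + diag_ev
    if diagnostics and on_error == "raise":
        listing = "; ".join(str(d) for d in diagnostics[:20])
        more = "" if len(diagnostics) <= 20 else f" (+{len(diagnostics) - 20} more)"
        raise SchemaError(f"{len(diagnostics)} invalid rows: {listing}{more}")
    prescriptions.sort(key=lambda r: (r.patient_id, r.issue_date))
    return ReadResult(
        patients=unique_patients,
        prescriptions=prescriptions,
        events=events,
        diagnostics=diagnostics,
        n_rows={"patients": n_p, "prescriptions": n_rx, "events": n_ev},
    )


def _fmt_date(d: dt.date | None) -> str:
    return "" if d is None else d.isoformat()


def write_patients(path, patients: Iterable[PatientRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PATIENT_COLUMNS)
        for p in patients:
            w.writerow(
                [
                    p.patient_id,
                    _fmt_date(p.enrollment_date),
                    _fmt_date(p.birth_date),
                    p.gender or "",
                    _fmt_date(p.art_start_date),
                    _fmt_date(p.transfer_out_date),
                    p.phone_status,
                    _fmt_date(p.phone_capture_date),
                    _fmt_date(p.opt_out_date),
                ]
            )


def write_prescriptions(path, prescriptions: Iterable[PrescriptionRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PRESCRIPTION_COLUMNS)
        for r in prescriptions:
            w.writerow(
                [
                    r.patient_id,
                    _fmt_date(r.issue_date),
                    r.duration_days,
                    serialize_agents(r.agents),
                    r.line,
                    int(r.fdc),
                ]
            )


def write_events(path, events: Iterable[ProgramEvent]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(EVENT_COLUMNS)
        for e in events:
            w.writerow(
                [
                    e.patient_id,
                    _fmt_date(e.intro_sms_date),
                    _fmt_date(e.opt_out_date),
                    e.delivery_confirmed_count,
                ]
            )


def write_tables(outdir, patients, prescriptions, events=None) -> dict:
    """Write the clinic tables under ``outdir``; returns the paths used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.csv",
        "prescriptions": outdir / "prescriptions.csv",
    }
    write_patients(paths["patients"], patients)
    write_prescriptions(paths["prescriptions"], prescriptions)
    if events is not None:
        paths["events"] = outdir / "events.csv"
        write_events(paths["events"], events)
    return paths
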