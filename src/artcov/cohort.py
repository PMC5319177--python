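"""Cohort construction: inclusion criteria, intention-to-treat groups,
missing-covariate imputation, and descriptive comparisons.

Exposure groups are a pure function of the phone fields captured before the
observation period: patients with a phone number captured into the program
database are *Exposed* (messages were sent, regardless of later opt-out or
delivery failure — intention to treat), patients whose chart showed no
number are *Unexposed*, and patients whose chart could not be reviewed are
*Unknown*.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .config import StudyConfig
from .coverage import (
    DURING_PROGRAM,
    PRE_PROGRAM,
    DailyCoverageSeries,
    ObservationWindow,
    compute_coverage,
    coverage_proportion,
    deduplicate,
    determine_window,
)
from .io import PatientRecord, PrescriptionRecord

GROUP_EXPOSED = "Exposed"
GROUP_UNEXPOSED = "Unexposed"
GROUP_UNKNOWN = "Unknown"
GROUPS = (GROUP_EXPOSED, GROUP_UNEXPOSED, GROUP_UNKNOWN)

SUBSET_FULL = "full"
SUBSET_BELOW_100 = "below_100_baseline"
SUBSET_RECENT = "recent_initiators"
SUBSETS = (SUBSET_FULL, SUBSET_BELOW_100, SUBSET_RECENT)

RECENT_INITIATOR_YEARS_DAYS = 730.5  # two 365.25-day years


class CohortError(ValueError):
    pass


@dataclass
class Covariates:
    """Patient-level fixed-effect inputs; ``None`` marks a missing value
    before imputation.  ``female`` is the 0/1 encoding of gender and may be
    fractional after mean imputation."""

    age_years: float | None
    female: float | None
    art_days_at_data_start: float | None
    missing_any: bool = False


@dataclass
class CohortMember:
    patient: PatientRecord
    group: str
    window: ObservationWindow
    coverage: DailyCoverageSeries
    covariates: Covariates
    pre_program_coverage: float | None = None
    exclusion_reason: str | None = None


@dataclass
class ExclusionTally:
    """Screening accounting; ``included`` must equal ``total_screened``
    minus the sum of the exclusion counts."""

    total_screened: int
    under_age: int
    no_rx_in_observation: int
    not_enrolled_before: int
    delayed_phone_capture: int
    no_observation_time: int
    included: int

    EXCLUSION_FIELDS = (
        "under_age",
        "no_rx_in_observation",
        "not_enrolled_before",
        "delayed_phone_capture",
        "no_observation_time",
    )

    def check(self) -> None:
        counts = [getattr(self, f) for f in self.EXCLUSION_FIELDS]
        if any(c < 0 for c in counts) or self.included < 0:
            raise CohortError("negative tally count")
        if self.included != self.total_screened - sum(counts):
            raise CohortError(
                f"tally does not conserve: {self.total_screened} screened, "
                f"{sum(counts)} excluded, {self.included} included"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("total_screened", self.total_screened)]
        rows += [(f, getattr(self, f)) for f in self.EXCLUSION_FIELDS]
        rows.append(("included", self.included))
        return pd.DataFrame(rows, columns=["reason", "count"])


def assign_group(patient: PatientRecord, config: StudyConfig) -> str:
    """Intention-to-treat group from the phone fields alone."""
    if patient.phone_status == "available":
        return GROUP_EXPOSED
    if patient.phone_status == "absent":
        return GROUP_UNEXPOSED
    return GROUP_UNKNOWN


def pre_program_coverage(member: CohortMember, config: StudyConfig) -> float | None:
    """Covered-day proportion over the window's pre-program days, or ``None``
    when the window starts at/after the program launch."""
    return coverage_proportion(member.coverage, PRE_PROGRAM)


def build_cohort(
    patients: Sequence[PatientRecord],
    prescriptions: Sequence[PrescriptionRecord],
    config: StudyConfig,
):
    """Apply the inclusion criteria and assemble cohort members.

    Exclusions are applied in a fixed order (adult age; a prescription in
    the observation period; enrollment before the observation period;
    phone capture before the observation period; a non-empty observation
    window) and each screened patient is counted once under the first
    criterion it fails.

    Returns
    -------
    (members, tally) : list[CohortMember], ExclusionTally
    """
    rx_by_patient: dict = {}
    for rec in prescriptions:
        rx_by_patient.setdefault(rec.patient_id, []).append(rec)
    for recs in rx_by_patient.values():
        recs.sort(key=lambda r: r.issue_date)

    counts = dict.fromkeys(ExclusionTally.EXCLUSION_FIELDS, 0)
    members: list = []
    for patient in patients:
        age = patient.age_years_at(config.data_start)
        if age is not None and age < config.adult_age_years:
            counts["under_age"] += 1
            continue
        kept, _ = deduplicate(rx_by_patient.get(patient.patient_id, []))
        if not any(
            config.obs_start <= r.issue_date <= config.data_end for r in kept
        ):
            counts["no_rx_in_observation"] += 1
            continue
        if patient.enrollment_date > config.obs_start:
            counts["not_enrolled_before"] += 1
            continue
        if (
            patient.phone_status == "available"
            and patient.phone_capture_date is not None
            and patient.phone_capture_date >= config.obs_start
        ):
            counts["delayed_phone_capture"] += 1
            continue
        window = determine_window(patient, kept, config)
        if window is None:
            counts["no_observation_time"] += 1
            continue
        series = compute_coverage(kept, window, config)
        member = CohortMember(
            patient=patient,
            group=assign_group(patient, config),
            window=window,
            coverage=series,
            covariates=Covariates(
                age_years=age,
                female=(
                    None
                    if patient.gender is None
                    else float(patient.gender == "female")
                ),
                art_days_at_data_start=float(
                    (config.data_start - patient.art_start_date).days
                ),
            ),
        )
        member.pre_program_coverage = pre_program_coverage(member, config)
        members.append(member)

    tally = ExclusionTally(
        total_screened=len(patients), included=len(members), **counts
    )
    tally.check()
    return members, tally


def impute_missing(members: Sequence[CohortMember]):
    """Mean-substitute missing non-prescription covariates in place.

    Cohort means are computed over included members with an available value;
    any member with at least one substituted value gets ``missing_any=True``
    (the indicator later offered to the model).  Raises if a covariate is
    missing for every member.
    """
    members = list(members)
    for name in ("age_years", "female", "art_days_at_data_start"):
        values = [
            getattr(m.covariates, name)
            for m in members
            if getattr(m.covariates, name) is not None
        ]
        if not values and members:
            raise CohortError(f"covariate {name} missing for all members")
        mean = float(np.mean(values)) if values else 0.0
        for m in members:
            if getattr(m.covariates, name) is None:
                setattr(m.covariates, name, mean)
                m.covariates.missing_any = True
    return members


def select_subset(
    members: Sequence[CohortMember], which: str, config: StudyConfig
) -> list:
    """Targeted sub-populations re-analyzed with the full-cohort method.

    ``below_100_baseline`` keeps members with observed pre-program coverage
    strictly below 100% (an undefined baseline cannot be below 100%);
    ``recent_initiators`` keeps members who started ART within two
    365.25-day years before the program launch (inclusive boundary).
    """
    if which == SUBSET_FULL:
        return list(members)
    if which == SUBSET_BELOW_100:
        return [
            m
            for m in members
            if m.pre_program_coverage is not None and m.pre_program_coverage < 1.0
        ]
    if which == SUBSET_RECENT:
        threshold = dt.datetime.combine(
            config.program_start, dt.time()
        ) - dt.timedelta(days=RECENT_INITIATOR_YEARS_DAYS)
        return [
            m
            for m in members
            if dt.datetime.combine(m.patient.art_start_date, dt.time()) >= threshold
        ]
    raise CohortError(f"unknown subset {which!r}; expected one of {SUBSETS}")


# ---------------------------------------------------------------------------
# descriptive comparisons


def _anova_p(groups: Sequence[np.ndarray]) -> float:
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        return float("nan")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # identical samples: no evidence of difference
        return 1.0
    stat, p = stats.f_oneway(*groups)
    return 1.0 if np.isnan(p) else float(p)


def _chi2_p(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    table = table[:, table.sum(axis=0) > 0]
    table = table[table.sum(axis=1) > 0, :]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _median_iqr(values: np.ndarray, fmt: str = "{:.1f}") -> str:
    if len(values) == 0:
        return "-"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{fmt.format(med)} ({fmt.format(q1)}–{fmt.format(q3)})"


def _n_pct(flags: np.ndarray) -> str:
    n = int(np.sum(flags))
    if len(flags) == 0:
        return "-"
    return f"{n:,} ({100.0 * n / len(flags):.1f}%)"


_RX_CATEGORIES = {30: "1-month", 60: "2-month", 90: "3-month", 180: "6-month"}
_RX_EDGES = np.array([30, 60, 90, 180])


def _rx_category(duration: int) -> str:
    nearest = _RX_EDGES[np.argmin(np.abs(_RX_EDGES - duration))]
    return _RX_CATEGORIES[int(nearest)]


def _first_observation_row(member: CohortMember) -> pd.Series:
    return member.coverage.frame.iloc[0]


def baseline_table(
    members: Sequence[CohortMember], config: StudyConfig
) -> pd.DataFrame:
    """Baseline-characteristics table with across-group and
    Exposed-vs-Unexposed p-values.

    Continuous rows show median (IQR) but are compared with one-way ANOVA;
    categorical rows show n (%) and are compared with the chi-squared test.
    Age and treatment duration are referenced to the start of data
    availability; prescription attributes to each member's first observed
    day.  Observed (pre-imputation) values are used.
    """
    by_group = {g: [m for m in members if m.group == g] for g in GROUPS}

    def _vals(g, getter):
        return np.array(
            [v for m in by_group[g] if (v := getter(m)) is not None], dtype=float
        )

    def _flags(g, getter):
        return np.array([bool(getter(m)) for m in by_group[g]])

    rows = []

    def continuous_row(label, getter, fmt="{:.1f}"):
        per_group = {g: _vals(g, getter) for g in GROUPS}
        rows.append(
            {
                "variable": label,
                **{g: _median_iqr(per_group[g], fmt) for g in GROUPS},
                "p_all": _anova_p([per_group[g] for g in GROUPS]),
                "p_exposed_vs_unexposed": _anova_p(
                    [per_group[GROUP_EXPOSED], per_group[GROUP_UNEXPOSED]]
                ),
            }
        )

    def categorical_row(label, getter):
        per_group = {g: _flags(g, getter) for g in GROUPS}
        table = np.array(
            [
                [np.sum(per_group[g]), np.sum(~per_group[g])]
                for g in GROUPS
            ]
        ).T
        two = table[:, :2]
        rows.append(
            {
                "variable": label,
                **{g: _n_pct(per_group[g]) for g in GROUPS},
                "p_all": _chi2_p(table),
                "p_exposed_vs_unexposed": _chi2_p(two),
            }
        )

    continuous_row("Age in years (IQR)", lambda m: m.covariates.age_years)
    categorical_row(
        "Female",
        lambda m: m.covariates.female is not None and m.covariates.female >= 0.5,
    )
    continuous_row(
        "ART duration in years (IQR)",
        lambda m: (
            None
            if m.covariates.art_days_at_data_start is None
            else m.covariates.art_days_at_data_start / 365.25
        ),
    )
    continuous_row(
        "Prescription length in days (IQR)",
        lambda m: float(_first_observation_row(m)["active_rx_duration_days"]),
        fmt="{:.0f}",
    )

    # one multi-category block: patients by prescription-length class
    cats = list(_RX_CATEGORIES.values())
    cat_of = {
        m.patient.patient_id: _rx_category(
            int(_first_observation_row(m)["active_rx_duration_days"])
        )
        for m in members
    }
    block = np.array(
        [
            [
                sum(cat_of[m.patient.patient_id] == c for m in by_group[g])
                for g in GROUPS
            ]
            for c in cats
        ]
    )
    p_block_all = _chi2_p(block)
    p_block_two = _chi2_p(block[:, :2])
    for i, c in enumerate(cats):
        rows.append(
            {
                "variable": f"{c} prescriptions",
                **{
                    g: (
                        f"{block[i, j]:,} "
                        f"({100.0 * block[i, j] / max(len(by_group[g]), 1):.1f}%)"
                    )
                    for j, g in enumerate(GROUPS)
                },
                "p_all": p_block_all if i == 0 else np.nan,
                "p_exposed_vs_unexposed": p_block_two if i == 0 else np.nan,
            }
        )

    categorical_row(
        "First line regimen",
        lambda m: _first_observation_row(m)["active_line"] == "first",
    )
    categorical_row(
        "Fixed dose combination", lambda m: bool(_first_observation_row(m)["active_fdc"])
    )
    categorical_row(
        "No pre-program observation time",
        lambda m: m.pre_program_coverage is None,
    )
    categorical_row(
        "Transfer out during observation",
        lambda m: m.patient.transfer_out_date is not None
        and m.window.start <= m.patient.transfer_out_date <= config.data_end,
    )
    return pd.DataFrame(rows)


def mcnemar_gt95(members: Sequence[CohortMember], threshold: float = 0.95):
    """Paired comparison of >95% coverage attainment pre vs during program.

    Restricted to members observed in both periods; exact two-sided
    binomial McNemar on the discordant pairs.

    Returns
    -------
    (statistic, p_value, table) where ``table`` is the 2x2 pre/during
    cross-classification.
    """
    table = np.zeros((2, 2), dtype=int)
    for m in members:
        pre = coverage_proportion(m.coverage, PRE_PROGRAM)
        during = coverage_proportion(m.coverage, DURING_PROGRAM)
        if pre is None or during is None:
            continue
        table[int(pre > threshold), int(during > threshold)] += 1
    if table[0, 1] + table[1, 0] == 0:  # no discordant pairs: no information
        return 0.0, 1.0, table
    res = _sm_mcnemar(table, exact=True)
    return float(res.statistic), float(res.pvalue), table
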