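"""Study-level configuration: calendar anchors and analysis constants.

The defaults encode the evaluation setting: pharmacy data available from
2012-11-04 through 2014-06-26, an observation period opening 2013-07-01,
and a weekly-SMS program launching 2013-09-09.  All intervals of days are
closed on both ends; a d-day prescription issued on day t covers
[t, t + d - 1].
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields

import yaml


class ConfigError(ValueError):
    """Raised for an internally inconsistent configuration."""


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class StudyConfig:
    """Calendar anchors and constants of the coverage analysis.

    Attributes
    ----------
    data_start, data_end : dt.date
        Span of pharmacy-record availability.  Age and treatment duration
        are referenced to ``data_start``.
    obs_start : dt.date
        First day of the observation period.
    program_start : dt.date
        First day of the SMS program; days before it are ``pre_program``,
        days on or after it are ``during_program``.
    carryover_cap_days : int
        Maximum number of leftover coverage days credited at a refill of
        an unchanged regimen (clinic policy: 30).
    adult_age_years : int
        Minimum age (at ``data_start``) for cohort inclusion.
    elimination_p : float
        Wald p-value threshold for backward elimination of candidate
        covariates.
    days_per_year : float
        Scale used when translating a coverage difference into days per
        year.
    """

    data_start: dt.date = dt.date(2012, 11, 4)
    data_end: dt.date = dt.date(2014, 6, 26)
    obs_start: dt.date = dt.date(2013, 7, 1)
    program_start: dt.date = dt.date(2013, 9, 9)
    carryover_cap_days: int = 30
    adult_age_years: int = 18
    elimination_p: float = 0.25
    days_per_year: float = 365.25

    def __post_init__(self) -> None:
        for name in ("data_start", "data_end", "obs_start", "program_start"):
            object.__setattr__(self, name, _parse_date(getattr(self, name)))
        if not (self.data_start < self.obs_start < self.program_start < self.data_end):
            raise ConfigError(
                "expected data_start < obs_start < program_start < data_end, got "
                f"{self.data_start} / {self.obs_start} / {self.program_start} / {self.data_end}"
            )
        if self.carryover_cap_days < 0:
            raise ConfigError("carryover_cap_days must be >= 0")
        if not 0.0 < self.elimination_p < 1.0:
            raise ConfigError("elimination_p must be in (0, 1)")

    @property
    def pre_program_end(self) -> dt.date:
        """Last pre-program day (the day before the program starts)."""
        return self.program_start - dt.timedelta(days=1)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "study" in doc:
            doc = doc["study"] or {}
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.isoformat() if isinstance(v, dt.date) else v
        return out


DEFAULT_CONFIG = StudyConfig()
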