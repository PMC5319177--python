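"""Patient-day analysis dataset, model fitting, backward elimination, and
the odds-ratio -> days-per-year translation.

The unit of observation is one patient-day, so each patient is weighted by
their length of observation.  The fitted model is

    logit P(covered) = b0 + covariates + gamma_period*during
                       + gamma_E*Exposed + gamma_U*Unknown
                       + delta_E*(Exposed x during) + delta_U*(Unknown x during)
                       + u_i,   u_i ~ N(0, sigma_u^2)

with reference levels group=Unexposed and period=pre_program, so every
reported contrast is a single coefficient: the group main effects are the
pre-program coverage differences and the interaction terms are the program
effects.  Group, period and their interaction are retained a priori; the
remaining covariates are candidates for stepwise backward elimination at a
Wald-p threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    GROUP_EXPOSED,
    GROUP_UNKNOWN,
    CohortMember,
    select_subset,
)
from .config import StudyConfig
from .coverage import DURING_PROGRAM, ContractError
from .mixedlogit import FitError, MixedLogitResult, fit_mixed_logit

A_PRIORI_TERMS = [
    "group_exposed",
    "group_unknown",
    "period_during",
    "exposed_x_during",
    "unknown_x_during",
]
CANDIDATE_TERMS = [
    "age_years",
    "female",
    "art_duration_30d",
    "rx_length_30d",
    "first_line",
    "fdc",
    "missing_any",
]

#: printed labels, in report order
TERM_LABELS = {
    "age_years": "Age (per year)",
    "female": "Female gender",
    "art_duration_30d": "Prior ART duration (per 30 days)",
    "rx_length_30d": "Prescription length (per 30 days)",
    "first_line": "First line regimen",
    "fdc": "Fixed dose combination",
    "missing_any": "Any missing covariate",
    "period_during": "During-program period",
    "group_exposed": "Pre-program coverage: Exposed vs. Unexposed",
    "group_unknown": "Pre-program coverage: Unknown vs. Unexposed",
    "exposed_x_during": "Program effect: Exposed vs. Unexposed",
    "unknown_x_during": "Program effect: Unknown vs. Unexposed",
}


class AnalysisError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Which terms enter the model; the a priori block is immutable."""

    candidate_terms: list = field(default_factory=lambda: list(CANDIDATE_TERMS))

    @property
    def retained_terms(self) -> list:
        return ["intercept"] + list(self.candidate_terms) + A_PRIORI_TERMS


def build_daily_dataset(
    members: Sequence[CohortMember], config: StudyConfig
) -> pd.DataFrame:
    """One row per member per in-window day, with time-varying covariates
    read off the coverage-series annotations (carried forward across
    uncovered gaps)."""
    frames = []
    for m in members:
        if m.window is None or m.coverage.n_days == 0:
            raise ContractError(f"member {m.patient.patient_id} has an empty window")
        cov = m.covariates
        if cov.age_years is None or cov.female is None or cov.art_days_at_data_start is None:
            raise ContractError(
                f"member {m.patient.patient_id} has unimputed covariates"
            )
        f = m.coverage.frame
        days_since_data_start = (
            f["date"] - np.datetime64(config.data_start)
        ).dt.days.to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": m.patient.patient_id,
                    "covered": f["covered"].to_numpy().astype(np.int8),
                    "period": f["period"].to_numpy(),
                    "group": m.group,
                    "age_years": cov.age_years,
                    "female": cov.female,
                    "art_duration_30d": (
                        cov.art_days_at_data_start + days_since_data_start
                    )
                    / 30.0,
                    "rx_length_30d": f["active_rx_duration_days"].to_numpy() / 30.0,
                    "first_line": (f["active_line"] == "first").to_numpy().astype(np.int8),
                    "fdc": f["active_fdc"].to_numpy().astype(np.int8),
                    "missing_any": np.int8(cov.missing_any),
                }
            )
        )
    if not frames:
        raise ContractError("no members")
    return pd.concat(frames, ignore_index=True)


def build_design(rows: pd.DataFrame, terms: Sequence[str]):
    """(y, X, names, groups) for the requested terms plus the a priori block."""
    n = len(rows)
    cols = {"intercept": np.ones(n)}
    for t in terms:
        if t in ("intercept",):
            continue
        elif t == "group_exposed":
            cols[t] = (rows["group"] == GROUP_EXPOSED).to_numpy(dtype=float)
        elif t == "group_unknown":
            cols[t] = (rows["group"] == GROUP_UNKNOWN).to_numpy(dtype=float)
        elif t == "period_during":
            cols[t] = (rows["period"] == DURING_PROGRAM).to_numpy(dtype=float)
        elif t == "exposed_x_during":
            cols[t] = (
                (rows["group"] == GROUP_EXPOSED) & (rows["period"] == DURING_PROGRAM)
            ).to_numpy(dtype=float)
        elif t == "unknown_x_during":
            cols[t] = (
                (rows["group"] == GROUP_UNKNOWN) & (rows["period"] == DURING_PROGRAM)
            ).to_numpy(dtype=float)
        else:
            cols[t] = rows[t].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    y = rows["covered"].to_numpy(dtype=float)
    return y, X, names, rows["patient_id"].to_numpy()


@dataclass
class ModelResult:
    """Coefficient table plus the derived program-effect contrasts."""

    fit: MixedLogitResult
    terms: list
    dropped_degenerate: list

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def random_intercept_variance(self) -> float:
        return self.fit.random_intercept_variance

    def table(self) -> pd.DataFrame:
        ci = self.fit.conf_int()
        return pd.DataFrame(
            {
                "term": self.fit.names,
                "coef": self.fit.params,
                "se": self.fit.se,
                "OR": np.exp(self.fit.params),
                "CI_low": np.exp(ci[:, 0]),
                "CI_high": np.exp(ci[:, 1]),
                "p": self.fit.pvalues,
            }
        )

    def _contrast(self, name: str) -> dict:
        if name not in self.fit.names:  # structurally absent in this subset
            return {"OR": np.nan, "CI_low": np.nan, "CI_high": np.nan, "p": np.nan}
        i = self.fit.names.index(name)
        ci = self.fit.conf_int()[i]
        return {
            "OR": float(np.exp(self.fit.params[i])),
            "CI_low": float(np.exp(ci[0])),
            "CI_high": float(np.exp(ci[1])),
            "p": float(self.fit.pvalues[i]),
        }

    @property
    def contrasts(self) -> dict:
        return {
            "OR_during_vs_pre": self._contrast("period_during"),
            "OR_pre_Exposed_vs_Unexposed": self._contrast("group_exposed"),
            "OR_pre_Unknown_vs_Unexposed": self._contrast("group_unknown"),
            "OR_program_Exposed": self._contrast("exposed_x_during"),
            "OR_program_Unknown": self._contrast("unknown_x_during"),
        }


def _split_degenerate(rows: pd.DataFrame, candidates: Sequence[str]):
    """Candidates without variation cannot be estimated; drop them up front."""
    keep, dropped = [], []
    for t in candidates:
        if rows[t].nunique() > 1:
            keep.append(t)
        else:
            dropped.append(t)
    return keep, dropped


def fit_model(
    rows: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_quad: int = 9,
    compute_se: bool = True,
) -> ModelResult:
    """Fit the random-intercept logistic model for the given term set.

    Requires at least two exposure groups and a non-constant outcome;
    non-convergence is carried on the result, never silently dropped.
    """
    if spec is None:
        spec = ModelSpec()
    if rows["group"].nunique() < 2:
        raise AnalysisError("fewer than 2 exposure groups present")
    candidates, dropped = _split_degenerate(rows, spec.candidate_terms)
    y, X, names, groups = build_design(rows, candidates + A_PRIORI_TERMS)
    # a priori contrast columns can still be structurally empty (e.g. a
    # subset without the Unknown group); such columns are unestimable and
    # removed with a record, like degenerate candidates
    variable = [
        i for i, n in enumerate(names) if n == "intercept" or np.ptp(X[:, i]) > 0
    ]
    dropped += [n for i, n in enumerate(names) if i not in variable]
    X = X[:, variable]
    names = [names[i] for i in variable]
    try:
        fit = fit_mixed_logit(
            y, X, groups, names=names, n_quad=n_quad, compute_se=compute_se
        )
    except FitError as exc:
        raise AnalysisError(str(exc)) from exc
    return ModelResult(fit=fit, terms=names, dropped_degenerate=dropped)


def backward_eliminate(
    rows: pd.DataFrame,
    spec: ModelSpec | None = None,
    p_threshold: float = 0.25,
    n_quad: int = 9,
):
    """Stepwise backward elimination of candidate covariates.

    Repeatedly refits, removing the single candidate with the largest Wald
    p-value above ``p_threshold``; group, period and their interaction are
    never considered.  Returns the final spec, its fitted model, and a log
    with one row per removal.
    """
    if spec is None:
        spec = ModelSpec()
    current = list(spec.candidate_terms)
    log_rows = []
    step = 0
    while True:
        result = fit_model(rows, ModelSpec(candidate_terms=current), n_quad=n_quad)
        present = [t for t in current if t in result.fit.names]
        pvals = {t: result.fit.wald_p(t) for t in present}
        over = {t: p for t, p in pvals.items() if p > p_threshold}
        if not over:
            for t in result.dropped_degenerate:
                log_rows.append(
                    {"step": step, "removed": t, "p": np.nan, "reason": "no variation"}
                )
            log = pd.DataFrame(
                log_rows, columns=["step", "removed", "p", "reason"]
            )
            return ModelSpec(candidate_terms=present), result, log
        step += 1
        worst = max(over, key=over.get)
        log_rows.append(
            {"step": step, "removed": worst, "p": over[worst], "reason": "p > threshold"}
        )
        current = [t for t in present if t != worst]


def absolute_risk_translation(
    p_avg: float, or_effect: float, days_per_year: float = 365.25
) -> float:
    """Translate an exposure odds ratio into days of coverage per year.

    From the observed average coverage ``p_avg``, divide the coverage odds
    by ``or_effect`` to obtain the hypothetical coverage without exposure;
    the difference, scaled by ``days_per_year``, is the absolute effect in
    days.  Positive when ``or_effect > 1``.
    """
    if not 0.0 < p_avg < 1.0:
        raise ValueError("p_avg must lie strictly between 0 and 1")
    if or_effect <= 0.0:
        raise ValueError("or_effect must be positive")
    odds = p_avg / (1.0 - p_avg)
    hypo_odds = odds / or_effect
    p_hypo = hypo_odds / (1.0 + hypo_odds)
    return (p_avg - p_hypo) * days_per_year


@dataclass
class AnalysisReport:
    subset: str
    n_members: int
    n_rows: int
    spec: ModelSpec
    result: ModelResult
    elimination_log: pd.DataFrame
    p_avg_exposed_during: float | None
    arr_days_per_year: float | None

    def table2(self) -> pd.DataFrame:
        """Publication-shaped report: one row per printed term, ordered as
        the model-output table, with eliminated covariates dashed out."""
        tab = self.result.table().set_index("term")
        rows = []
        for term in list(CANDIDATE_TERMS) + [
            "period_during",
            "group_exposed",
            "group_unknown",
            "exposed_x_during",
            "unknown_x_during",
        ]:
            label = TERM_LABELS[term]
            if term in tab.index:
                r = tab.loc[term]
                rows.append(
                    {
                        "term": label,
                        "OR": r["OR"],
                        "CI_low": r["CI_low"],
                        "CI_high": r["CI_high"],
                        "p": r["p"],
                    }
                )
            else:
                rows.append(
                    {
                        "term": label,
                        "OR": np.nan,
                        "CI_low": np.nan,
                        "CI_high": np.nan,
                        "p": np.nan,
                    }
                )
        return pd.DataFrame(rows)


def run_analysis(
    members: Sequence[CohortMember],
    config: StudyConfig,
    subset: str = "full",
    n_quad: int = 9,
) -> AnalysisReport:
    """Subset selection -> daily dataset -> elimination -> final fit ->
    absolute-effect translation, on one shared code path."""
    selected = select_subset(members, subset, config)
    if not selected:
        raise AnalysisError(f"subset {subset!r} is empty")
    rows = build_daily_dataset(selected, config)
    spec, result, log = backward_eliminate(
        rows, p_threshold=config.elimination_p, n_quad=n_quad
    )
    exposed_during = rows[
        (rows["group"] == GROUP_EXPOSED) & (rows["period"] == DURING_PROGRAM)
    ]
    p_avg = arr = None
    if len(exposed_during) and "exposed_x_during" in result.fit.names:
        p_avg = float(exposed_during["covered"].mean())
        if 0.0 < p_avg < 1.0:
            arr = absolute_risk_translation(
                p_avg,
                result.contrasts["OR_program_Exposed"]["OR"],
                config.days_per_year,
            )
    return AnalysisReport(
        subset=subset,
        n_members=len(selected),
        n_rows=len(rows),
        spec=spec,
        result=result,
        elimination_log=log,
        p_avg_exposed_during=p_avg,
        arr_days_per_year=arr,
    )
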