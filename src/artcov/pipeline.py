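"""End-to-end analysis run with a manifest.

``run_pipeline`` executes read -> dedup/window/coverage -> cohort ->
descriptives -> model (full cohort plus the configured subsets) -> absolute
effect, writing publication-shaped CSV outputs (plus aligned-text
renderings) and exactly one JSON manifest per run.  Outputs are fully
deterministic given inputs, configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    GROUPS,
    SUBSETS,
    baseline_table,
    build_cohort,
    impute_missing,
    mcnemar_gt95,
)
from .config import StudyConfig
from .coverage import DURING_PROGRAM, PRE_PROGRAM, coverage_proportion, export_coverage
from .glmm import run_analysis
from .io import read_tables


class PipelineError(RuntimeError):
    pass


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def coverage_histogram(members, bin_width: float = 5.0) -> pd.DataFrame:
    """Binned per-patient coverage distribution by group and period.

    Percent-coverage bins of ``bin_width`` points; diffable stand-in for a
    rendered histogram figure.
    """
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    rows = []
    for period in (PRE_PROGRAM, DURING_PROGRAM):
        for group in GROUPS:
            vals = [
                100.0 * v
                for m in members
                if m.group == group
                and (v := coverage_proportion(m.coverage, period)) is not None
            ]
            counts, _ = np.histogram(vals, bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append(
                    {
                        "period": period,
                        "group": group,
                        "bin_low_pct": lo,
                        "bin_high_pct": hi,
                        "n_patients": int(c),
                    }
                )
    return pd.DataFrame(rows)


def _write_text(frame: pd.DataFrame, path: Path, float_format="%.4g") -> None:
    with open(path, "w") as fh:
        fh.write(frame.to_string(index=False, float_format=lambda v: float_format % v))
        fh.write("\n")


def _write_pair(frame: pd.DataFrame, outdir: Path, stem: str) -> None:
    frame.to_csv(outdir / f"{stem}.csv", index=False, float_format="%.6g")
    _write_text(frame, outdir / f"{stem}.txt")


def run_pipeline(
    patients_path,
    prescriptions_path,
    outdir,
    events_path=None,
    config: StudyConfig | None = None,
    subsets=SUBSETS,
    export_daily: bool = False,
    n_quad: int = 7,
) -> dict:
    """Execute the full analysis and write artifacts under ``outdir``.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    failure is recorded in the manifest and re-raised as
    :class:`PipelineError`.
    """
    config = config or StudyConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
        "failed_stage": None,
    }
    stage = "read"
    t_all = time.time()
    try:
        t0 = time.time()
        manifest["inputs"]["patients"] = _sha256(patients_path)
        manifest["inputs"]["prescriptions"] = _sha256(prescriptions_path)
        if events_path is not None:
            manifest["inputs"]["events"] = _sha256(events_path)
        tables = read_tables(
            patients_path, prescriptions_path, events_path, config=config
        )
        manifest["stages"]["read"] = {
            "seconds": round(time.time() - t0, 3),
            "rows": tables.n_rows,
            "rejected": len(tables.diagnostics),
        }

        stage = "cohort"
        t0 = time.time()
        members, tally = build_cohort(tables.patients, tables.prescriptions, config)
        impute_missing(members)
        tally.to_frame().to_csv(outdir / "exclusions.csv", index=False)
        manifest["stages"]["cohort"] = {
            "seconds": round(time.time() - t0, 3),
            "tally": {
                r.reason: int(r.count) for r in tally.to_frame().itertuples()
            },
        }
        if not members:
            raise PipelineError("no members after inclusion criteria")

        stage = "descriptives"
        t0 = time.time()
        _write_pair(baseline_table(members, config), outdir, "table1")
        coverage_histogram(members).to_csv(
            outdir / "coverage_distribution.csv", index=False
        )
        stat, pval, tab = mcnemar_gt95(members)
        pd.DataFrame(
            [
                {
                    "n_pairs": int(tab.sum()),
                    "discordant_lost": int(tab[1, 0]),
                    "discordant_gained": int(tab[0, 1]),
                    "statistic": stat,
                    "p_value": pval,
                }
            ]
        ).to_csv(outdir / "mcnemar_gt95.csv", index=False)
        if export_daily:
            export_coverage(
                outdir / "daily_coverage.csv", [m.coverage for m in members]
            )
        manifest["stages"]["descriptives"] = {"seconds": round(time.time() - t0, 3)}

        subset_rows = []
        for subset in subsets:
            stage = f"model_{subset}"
            t0 = time.time()
            report = run_analysis(members, config, subset=subset, n_quad=n_quad)
            _write_pair(report.table2(), outdir, f"table2_{subset}")
            report.elimination_log.to_csv(
                outdir / f"elimination_{subset}.csv", index=False
            )
            subset_rows.append(
                {
                    "subset": subset,
                    "n_members": report.n_members,
                    "n_rows": report.n_rows,
                    "p_avg_exposed_during": report.p_avg_exposed_during,
                    "arr_days_per_year": report.arr_days_per_year,
                }
            )
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 3),
                "n_members": report.n_members,
                "n_rows": report.n_rows,
                "converged": report.result.converged,
                "sigma_u": report.result.fit.sigma_u,
                "arr_days_per_year": report.arr_days_per_year,
            }
        _write_pair(pd.DataFrame(subset_rows), outdir, "absolute_effect")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest["seconds_total"] = round(time.time() - t_all, 3)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["seconds_total"] = round(time.time() - t_all, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
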