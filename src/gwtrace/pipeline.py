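"""End-to-end report assembly: summaries → exceedance → seasonal tests →
ordination → risk.

``run_full_pipeline`` is a pure function of (input data, configuration): it
returns all stage outputs as DataFrames and optionally writes them under an
output directory as CSV (6 significant digits), JSON (full precision) and/or
a human-readable text digest. Reruns produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import multivariate, risk, summary
from .datamodel import (
    ANALYTES,
    AREAS,
    DEFAULT_COHORTS,
    GuidelineRegistry,
    SCOPES,
    ValidationError,
    WellSummary,
)
from .fixture import load_study_fixture
from .io import read_records_csv

log = logging.getLogger("gwtrace.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_csv`` (a monitoring-campaign CSV) or
    ``use_fixture`` must be set. ``formats`` ⊆ {csv, json, text}.
    """

    input_csv: str | Path | None = None
    use_fixture: bool = False
    limit_standard: str = "WHO"
    registry: GuidelineRegistry = field(default_factory=GuidelineRegistry.who_default)
    cohorts: tuple = DEFAULT_COHORTS
    out_dir: str | Path | None = None
    formats: tuple[str, ...] = ("csv",)
    c_rounding: str = "printed"

    def __post_init__(self) -> None:
        if bool(self.input_csv) == bool(self.use_fixture):
            raise ValidationError("exactly one of input_csv / use_fixture is required")
        if not self.formats:
            raise ValidationError("at least one output format is required")
        unknown = set(self.formats) - {"csv", "json", "text"}
        if unknown:
            raise ValidationError(f"unknown output format(s): {sorted(unknown)}")


def _load_summaries(config: RunConfig) -> list[WellSummary]:
    if config.use_fixture:
        log.info("loading packaged study fixture")
        return list(load_study_fixture().summaries)
    records = read_records_csv(config.input_csv)
    log.info("read %d monitoring records from %s", len(records), config.input_csv)
    return summary.summarize_records(records)


def run_full_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every analysis stage; return {stage name: tidy DataFrame}."""
    summaries = _load_summaries(config)
    log.info("working with %d well summaries", len(summaries))
    tables: dict[str, pd.DataFrame] = {}

    tables["well_summaries"] = pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries]
    ).rename(columns={"mean": "mean_ugL", "sd": "sd_ugL", "min": "min_ugL", "max": "max_ugL"})

    rows = []
    for analyte in ANALYTES:
        mean, sd = summary.metropolis_mean(summaries, analyte)
        rows.append(
            {"analyte": analyte, "area": "metropolis", "mean_ugL": mean, "sd_ugL": sd}
        )
        for area in AREAS:
            rows.append(
                {
                    "analyte": analyte,
                    "area": area,
                    "mean_ugL": summary.area_mean(summaries, analyte, area),
                    "sd_ugL": np.nan,
                }
            )
    tables["area_means"] = pd.DataFrame(rows)

    rows = []
    for analyte in ANALYTES:
        limit = config.registry.limit(config.limit_standard, analyte)
        for scope in SCOPES:
            rep = summary.exceedance(summaries, analyte, limit, scope=scope)
            rows.append(
                {
                    "analyte": analyte,
                    "scope": scope,
                    "limit_ugL": rep.limit,
                    "inclusive": rep.inclusive,
                    "n_wells": rep.n_wells,
                    "n_exceeding": rep.n_exceeding,
                    "fraction": rep.fraction,
                    "detection_frequency": summary.detection_frequency(
                        summaries, analyte, scope
                    ),
                }
            )
    tables["exceedance"] = pd.DataFrame(rows)
    log.info("exceedance computed at %s limits", config.limit_standard)

    rows = []
    for analyte in ANALYTES:
        res = summary.paired_seasonal_ttest(summaries, analyte)
        rows.append(
            {
                "analyte": analyte,
                "t_statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "alpha": res.alpha,
                "significant": res.significant,
                "pearson_r": res.pearson_r,
            }
        )
    tables["seasonal_tests"] = pd.DataFrame(rows)

    order, totals, tie = multivariate.prevalence_order(summaries)
    tables["prevalence"] = pd.DataFrame(
        [
            {"rank": i + 1, "analyte": a, "total_ugL": totals[a], "tie": tie}
            for i, a in enumerate(order)
        ]
    )
    log.info("prevalence order: %s", " > ".join(order))

    X, wells, cols = multivariate.matrix_from_summaries(summaries)
    ords = []
    try:
        ords.append(multivariate.pca(X, standardize=True, row_labels=wells, col_labels=cols))
    except ValidationError as exc:  # e.g. a constant analyte column
        log.warning("PCA skipped: %s", exc)
    ords.append(multivariate.correspondence_analysis(X, row_labels=wells, col_labels=cols))
    frac_rows, coord_rows = [], []
    for res in ords:
        for i, frac in enumerate(res.explained_fraction):
            frac_rows.append(
                {
                    "method": res.method,
                    "component": i + 1,
                    "explained_fraction": float(frac),
                    "total": res.total,
                }
            )
        for labels, coords, kind in (
            (res.row_labels, res.row_coords, "well"),
            (res.col_labels, res.col_coords, "analyte"),
        ):
            for label, coord in zip(labels, coords):
                row = {"method": res.method, "kind": kind, "label": label}
                row.update({f"dim{j + 1}": float(c) for j, c in enumerate(coord)})
                coord_rows.append(row)
    tables["ordination_variance"] = pd.DataFrame(frac_rows)
    tables["ordination_coords"] = pd.DataFrame(coord_rows)

    results = risk.risk_table(
        summaries, config.registry, cohorts=config.cohorts, c_rounding=config.c_rounding
    )
    tables["risk"] = pd.DataFrame(
        [
            {
                "area": r.area,
                "cohort": r.cohort,
                "analyte": r.analyte,
                "C_mgL": r.concentration_mg_l,
                "ADD_mg_kg_day": r.add,
                "RfD_mg_kg_day": r.rfd,
                "HQ": r.hq,
                "HI": r.hi,
            }
            for r in results
        ]
    )
    log.info("risk table: %d rows, %d scenarios", len(results), len(results) // len(ANALYTES))

    if config.out_dir is not None:
        _write_outputs(tables, config)
    return tables


def _json_safe(frame: pd.DataFrame) -> list[dict]:
    return json.loads(frame.to_json(orient="records"))


def _write_outputs(tables: dict[str, pd.DataFrame], config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        if "csv" in config.formats:
            frame.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
        if "json" in config.formats:
            (out / f"{name}.json").write_text(
                json.dumps(_json_safe(frame), indent=1, sort_keys=True) + "\n",
                encoding="utf-8",
            )
    if "text" in config.formats:
        (out / "report.txt").write_text(_text_digest(tables), encoding="utf-8")
    log.info("wrote %d tables to %s (%s)", len(tables), out, ", ".join(config.formats))


def _text_digest(tables: dict[str, pd.DataFrame]) -> str:
    lines = ["groundwater trace-element report", "=" * 34, ""]
    am = tables["area_means"]
    for _, row in am[am.area == "metropolis"].iterrows():
        lines.append(
            f"{row.analyte:>9}: metropolis mean {row.mean_ugL:.3g} ± {row.sd_ugL:.3g} μg/L"
        )
    lines.append("")
    for _, row in tables["exceedance"].query("scope == 'overall'").iterrows():
        lines.append(
            f"{row.analyte:>9}: {row.n_exceeding}/{row.n_wells} wells over "
            f"{row.limit_ugL:g} μg/L ({100 * row.fraction:.1f}%)"
        )
    lines.append("")
    for _, row in tables["seasonal_tests"].iterrows():
        verdict = "significant" if row.significant else "not significant"
        lines.append(
            f"{row.analyte:>9}: dry vs wet t={row.t_statistic:.3g} "
            f"(df={row.df}, p={row.p_value:.3g}) — {verdict}"
        )
    lines.append("")
    prevalence = " > ".join(tables["prevalence"].sort_values("rank").analyte)
    lines.append(f"prevalence order: {prevalence}")
    lines.append("")
    hi = tables["risk"].drop_duplicates(["area", "cohort"])
    for _, row in hi.iterrows():
        lines.append(f"HI {row.area}/{row.cohort}: {row.HI:.4f}")
    return "\n".join(lines) + "\n"
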