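"""Core data model for a groundwater trace-element monitoring study.

The study design: 35 open dug wells sampled monthly (3 months per season,
wet and dry) for three analytes — arsenic, antimony, selenium — reported in
μg/L. Wells belong to one of four land-use areas. Concentrations below the
instrument detection limit are recorded as 0 and flagged as non-detects.

All other modules consume the types defined here. Concentrations are carried
in μg/L everywhere except at the risk-module boundary, where a single
explicit conversion to mg/L happens (:func:`to_mg_per_L`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

AREAS = ("residential", "commercial", "industrial", "agricultural")
SEASONS = ("wet", "dry")
ANALYTES = ("arsenic", "antimony", "selenium")
SCOPES = ("overall", "wet", "dry")


class ValidationError(ValueError):
    """Input data violates a documented contract."""


class SchemaError(ValidationError):
    """A tabular input does not match the documented schema."""


class ConfigurationError(ValidationError):
    """A registry/config object is missing a required entry."""


class IntegrityError(RuntimeError):
    """Packaged fixture content does not match its recorded checksum."""


def _check_membership(value: str, allowed: tuple[str, ...], what: str) -> None:
    if value not in allowed:
        raise ValidationError(f"unknown {what} {value!r}; expected one of {allowed}")


@dataclass(frozen=True)
class MonitoringRecord:
    """One concentration observation from one well in one month.

    ``nondetect`` is equivalent to ``concentration == 0`` — the study records
    below-detection-limit measurements as zeros, and the equivalence is
    enforced on construction.
    """

    well_id: str
    area: str
    season: str
    analyte: str
    concentration: float  # μg/L
    nondetect: bool = False
    month_index: int | None = None  # 1–3 within the season, when known

    def __post_init__(self) -> None:
        _check_membership(self.area, AREAS, "area")
        _check_membership(self.season, SEASONS, "season")
        _check_membership(self.analyte, ANALYTES, "analyte")
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise ValidationError(
                f"concentration must be finite and >= 0, got {self.concentration!r}"
            )
        if self.nondetect != (self.concentration == 0):
            raise ValidationError(
                "nondetect flag must hold exactly when concentration == 0 "
                f"(got nondetect={self.nondetect}, concentration={self.concentration})"
            )
        if self.month_index is not None and not 1 <= int(self.month_index) <= 3:
            raise ValidationError(f"month_index must be in 1..3, got {self.month_index}")


@dataclass(frozen=True)
class WellSummary:
    """Per-well, per-analyte concentration summary (μg/L).

    ``scope`` is ``"overall"`` (pooled across both seasons) or one season.
    ``min``/``max`` may be None when the underlying monthly values are not
    available (seasonal rows of the packaged fixture carry mean and SD only).
    """

    well_id: str
    analyte: str
    scope: str
    mean: float
    sd: float
    n: int
    min: float | None = None
    max: float | None = None
    area: str | None = None

    def __post_init__(self) -> None:
        _check_membership(self.scope, SCOPES, "scope")
        _check_membership(self.analyte, ANALYTES, "analyte")
        if self.area is not None:
            _check_membership(self.area, AREAS, "area")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.min is not None and self.max is not None:
            if not self.min <= self.mean <= self.max:
                raise ValidationError(
                    f"{self.well_id}/{self.analyte}/{self.scope}: require "
                    f"min <= mean <= max, got {self.min} / {self.mean} / {self.max}"
                )


@dataclass(frozen=True)
class CohortParams:
    """Drinking-water exposure parameters for a population group.

    DW — daily water intake (L/day); BW — body weight (kg). Defaults follow
    the US EPA-style point estimates used in the study: adults drink 2.0 L/day
    at 50 kg, children 1.0 L/day at 20 kg.
    """

    name: str
    daily_water_l: float  # DW
    body_weight_kg: float  # BW

    def __post_init__(self) -> None:
        if self.daily_water_l <= 0:
            raise ValidationError("daily water intake DW must be > 0")
        if self.body_weight_kg <= 0:
            raise ValidationError("body weight BW must be > 0")


ADULT = CohortParams("adult", daily_water_l=2.0, body_weight_kg=50.0)
CHILD = CohortParams("child", daily_water_l=1.0, body_weight_kg=20.0)
DEFAULT_COHORTS = (ADULT, CHILD)


@dataclass(frozen=True)
class GuidelineRegistry:
    """Named drinking-water limit sets (μg/L) and oral reference doses.

    RfD values are chronic oral reference doses in mg/kg/day.
    """

    limits: Mapping[str, Mapping[str, float]]
    rfd: Mapping[str, float]

    def __post_init__(self) -> None:
        for standard, per_analyte in self.limits.items():
            for analyte, value in per_analyte.items():
                if value <= 0:
                    raise ValidationError(
                        f"limit {standard}/{analyte} must be > 0, got {value}"
                    )
        for analyte, value in self.rfd.items():
            if value <= 0:
                raise ValidationError(f"RfD for {analyte} must be > 0, got {value}")

    def limit(self, standard: str, analyte: str) -> float:
        try:
            return float(self.limits[standard][analyte])
        except KeyError as exc:
            raise ConfigurationError(
                f"no limit registered for standard={standard!r}, analyte={analyte!r}"
            ) from exc

    def rfd_for(self, analyte: str) -> float:
        try:
            return float(self.rfd[analyte])
        except KeyError as exc:
            raise ConfigurationError(f"no RfD registered for analyte {analyte!r}") from exc

    @classmethod
    def who_default(cls) -> "GuidelineRegistry":
        """WHO drinking-water limits (As 10, Sb 20, Se 40 μg/L) and the
        study's reference doses (As 3e-4, Sb 4e-4, Se 5e-3 mg/kg/day)."""
        return cls(
            limits={"WHO": {"arsenic": 10.0, "antimony": 20.0, "selenium": 40.0}},
            rfd={"arsenic": 0.0003, "antimony": 0.0004, "selenium": 0.005},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GuidelineRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "limits" not in raw or "rfd" not in raw:
            raise ConfigurationError(
                f"registry file {path} must contain 'limits' and 'rfd' mappings"
            )
        return cls(limits=raw["limits"], rfd=raw["rfd"])


@dataclass(frozen=True)
class ExceedanceReport:
    """Guideline-exceedance count over monitored wells."""

    analyte: str
    scope: str
    limit: float  # μg/L
    inclusive: bool
    n_wells: int
    n_exceeding: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_exceeding <= self.n_wells:
            raise ValidationError("require 0 <= n_exceeding <= n_wells")

    @property
    def fraction(self) -> float:
        return self.n_exceeding / self.n_wells


@dataclass(frozen=True)
class SeasonalTestResult:
    """Paired wet-vs-dry comparison for one analyte."""

    analyte: str
    statistic: float
    df: int
    p_value: float
    alpha: float
    pearson_r: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class RiskResult:
    """One analyte row of the risk table for an area × cohort scenario.

    ADD = DW·C/BW (mg/kg/day), HQ = ADD/RfD, HI = Σ HQ over the scenario's
    analytes; the scenario HI is repeated on each of its analyte rows.
    """

    area: str
    cohort: str
    analyte: str
    concentration_mg_l: float
    add: float
    rfd: float
    hq: float
    hi: float

    @property
    def adverse_possible(self) -> bool:
        """HQ above 1 flags possible non-carcinogenic adverse effects."""
        return self.hq > 1.0

    @property
    def hq_above_2(self) -> bool:
        return self.hq > 2.0


@dataclass
class OrdinationResult:
    """Output of a PCA or correspondence-analysis ordination."""

    method: str  # "pca" | "ca"
    row_labels: list[str]
    col_labels: list[str]
    row_coords: np.ndarray  # rows × k
    col_coords: np.ndarray  # cols × k
    explained_fraction: np.ndarray  # per component, sums to 1
    total: float  # total variance (PCA) or total inertia (CA)
    filtered_rows: list[str] = field(default_factory=list)


def to_mg_per_L(concentration_ug_l: float) -> float:
    """Convert a μg/L concentration to mg/L (exact division by 1000)."""
    if concentration_ug_l < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration_ug_l}")
    return concentration_ug_l / 1000.0


def iter_validated(records: Iterable[MonitoringRecord]) -> list[MonitoringRecord]:
    """Materialise records, additionally checking the well→area mapping is constant."""
    out: list[MonitoringRecord] = []
    seen: dict[str, str] = {}
    for rec in records:
        prev = seen.setdefault(rec.well_id, rec.area)
        if prev != rec.area:
            raise ValidationError(
                f"well {rec.well_id} appears with conflicting areas {prev!r} and {rec.area!r}"
            )
        out.append(rec)
    return out
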