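"""Non-carcinogenic risk cascade: ADD → HQ → HI.

For a cohort drinking DW litres per day at body weight BW kg, exposure to a
dissolved contaminant at concentration C (mg/L) gives the average daily dose

    ADD = DW · C / BW          (mg/kg/day)

The hazard quotient compares that dose with the chronic oral reference dose,
HQ = ADD / RfD, and the hazard index sums the quotients of co-occurring
contaminants for one exposure scenario, HI = Σ HQ. HQ (or HI) above 1 flags
possible non-carcinogenic adverse effects; the flags for both the >1 and the
more conservative >2 screen are exposed without interpretation.

Concentrations enter this module in mg/L. ``risk_table`` is the end-to-end
driver reproducing the study's area × cohort risk table from per-well
summaries; see its ``c_rounding`` note for the concentration-rounding
convention that table uses.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .datamodel import (
    ANALYTES,
    AREAS,
    CohortParams,
    ConfigurationError,
    DEFAULT_COHORTS,
    GuidelineRegistry,
    RiskResult,
    ValidationError,
    WellSummary,
    to_mg_per_L,
)
from .summary import area_mean


def average_daily_dose(concentration_mg_l: float, cohort: CohortParams) -> float:
    """ADD = DW·C/BW in mg/kg/day, at full floating precision."""
    if concentration_mg_l < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration_mg_l}")
    return cohort.daily_water_l * concentration_mg_l / cohort.body_weight_kg


def hazard_quotient(add: float, rfd: float) -> float:
    """HQ = ADD/RfD (dimensionless)."""
    if rfd <= 0:
        raise ValidationError(f"RfD must be > 0, got {rfd}")
    if add < 0:
        raise ValidationError(f"ADD must be >= 0, got {add}")
    return add / rfd


def hazard_index(hqs: Iterable[float]) -> float:
    """HI = Σ HQ over the scenario's analytes (order-independent exact sum)."""
    hqs = list(hqs)
    if not hqs:
        raise ValidationError("need at least one HQ")
    return float(sum(sorted(hqs)))


def _round_half_up(value: Decimal, exponent: Decimal) -> Decimal:
    return value.quantize(exponent, rounding=ROUND_HALF_UP)


def printed_concentration(mean_ug_l: Decimal | float | str) -> float:
    """Area-mean concentration rounded the way the study's risk table prints C.

    The published C column equals the exact area mean (μg/L) rounded half-up
    to 3 significant figures and then to 2 decimal places, converted to mg/L
    (e.g. 0.64625 → 0.646 → 0.65 μg/L → 0.00065 mg/L; 30.66 → 30.7 μg/L →
    0.0307 mg/L). Decimal arithmetic avoids binary-float half-way artefacts
    such as 13.35 → 13.3.
    """
    dec = Decimal(str(mean_ug_l))
    if dec < 0:
        raise ValidationError(f"concentration must be >= 0, got {mean_ug_l}")
    if dec != 0:
        shift = dec.adjusted()  # exponent of the leading digit
        dec = _round_half_up(dec, Decimal(1).scaleb(shift - 2))
    dec = _round_half_up(dec, Decimal("0.01"))
    return float(dec / 1000)


def risk_table(
    summaries: Iterable[WellSummary],
    registry: GuidelineRegistry,
    areas: Sequence[str] = AREAS,
    cohorts: Sequence[CohortParams] = DEFAULT_COHORTS,
    analytes: Sequence[str] = ANALYTES,
    c_rounding: str = "printed",
    area_means_ug_l: dict[tuple[str, str], float] | None = None,
) -> list[RiskResult]:
    """Full ADD/HQ/HI cascade per analyte × land-use area × cohort.

    C is the unweighted mean of per-well overall means within each area,
    converted to mg/L. ``c_rounding="printed"`` (default) applies the
    published table's concentration rounding before the cascade so results
    are comparable digit-for-digit with that table; ``"none"`` keeps full
    floating precision throughout. ``area_means_ug_l`` overrides computed
    area means (keyed by (area, analyte)), e.g. for simulated campaigns.
    """
    if c_rounding not in ("printed", "none"):
        raise ValidationError(f"c_rounding must be 'printed' or 'none', got {c_rounding!r}")
    summaries = list(summaries)
    for analyte in analytes:
        registry.rfd_for(analyte)  # fail fast, naming the missing analyte

    results: list[RiskResult] = []
    for area in areas:
        if area not in AREAS:
            raise ConfigurationError(f"unknown area {area!r}")
        concs: dict[str, float] = {}
        for analyte in analytes:
            if area_means_ug_l is not None:
                mean_ug = area_means_ug_l[(area, analyte)]
            else:
                mean_ug = area_mean(summaries, analyte, area)
            if c_rounding == "printed":
                concs[analyte] = printed_concentration(mean_ug)
            else:
                concs[analyte] = to_mg_per_L(mean_ug)
        for cohort in cohorts:
            adds = {a: average_daily_dose(concs[a], cohort) for a in analytes}
            hqs = {a: hazard_quotient(adds[a], registry.rfd_for(a)) for a in analytes}
            hi = hazard_index(hqs.values())
            for analyte in analytes:
                results.append(
                    RiskResult(
                        area=area,
                        cohort=cohort.name,
                        analyte=analyte,
                        concentration_mg_l=concs[analyte],
                        add=adds[analyte],
                        rfd=registry.rfd_for(analyte),
                        hq=hqs[analyte],
                        hi=hi,
                    )
                )
    return results


def hazard_indices(results: Iterable[RiskResult]) -> dict[tuple[str, str], float]:
    """Map (area, cohort) → HI from a risk-table result set."""
    out: dict[tuple[str, str], float] = {}
    for r in results:
        out[(r.area, r.cohort)] = r.hi
    return out
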