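"""Descriptive and comparative statistics over well summaries.

Operations take iterables of :class:`~gwtrace.datamodel.WellSummary` (as
produced by :func:`summarize_records` or the packaged fixture). Unless noted
otherwise a "mean" is the unweighted mean over wells — the study's claims
about detection, exceedance and city-wide averages all count wells, not
individual monthly samples.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    AREAS,
    SEASONS,
    ExceedanceReport,
    MonitoringRecord,
    SeasonalTestResult,
    ValidationError,
    WellSummary,
)


def summarize_records(records: Iterable[MonitoringRecord]) -> list[WellSummary]:
    """Collapse monthly monitoring records into per-well summaries.

    Produces one summary per well × analyte × scope. Seasonal summaries are
    plain mean/SD/min/max over that season's monthly values; the overall mean
    is defined as the unweighted mean of the two seasonal means (identical to
    the pooled mean under the balanced 3+3 monthly design, and the convention
    the study's overall table follows). Non-detects enter as zeros.
    """
    by_key: dict[tuple[str, str, str], list[float]] = defaultdict(list)
    area_of: dict[str, str] = {}
    for rec in records:
        area_of[rec.well_id] = rec.area
        by_key[(rec.well_id, rec.analyte, rec.season)].append(rec.concentration)

    out: list[WellSummary] = []
    wells_analytes = sorted({(w, a) for (w, a, _s) in by_key})
    for well, analyte in wells_analytes:
        season_means = []
        all_values: list[float] = []
        for season in SEASONS:
            values = by_key.get((well, analyte, season))
            if not values:
                continue
            arr = np.asarray(values, dtype=float)
            season_means.append(arr.mean())
            all_values.extend(values)
            out.append(
                WellSummary(
                    well_id=well,
                    analyte=analyte,
                    scope=season,
                    mean=float(arr.mean()),
                    sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                    min=float(arr.min()),
                    max=float(arr.max()),
                    n=int(arr.size),
                    area=area_of[well],
                )
            )
        arr = np.asarray(all_values, dtype=float)
        overall_mean = float(np.mean(season_means))
        out.append(
            WellSummary(
                well_id=well,
                analyte=analyte,
                scope="overall",
                mean=overall_mean,
                sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                min=float(arr.min()),
                max=float(arr.max()),
                n=int(arr.size),
                area=area_of[well],
            )
        )
    return out


def _per_well_means(
    summaries: Iterable[WellSummary], analyte: str, scope: str
) -> dict[str, WellSummary]:
    """One summary per well for the requested analyte/scope, keyed by well."""
    selected: dict[str, WellSummary] = {}
    for s in summaries:
        if s.analyte == analyte and s.scope == scope:
            if s.well_id in selected:
                raise ValidationError(
                    f"multiple {scope!r} summaries for well {s.well_id}, analyte {analyte}"
                )
            selected[s.well_id] = s
    if not selected:
        raise ValidationError(f"no {scope!r} summaries for analyte {analyte!r}")
    return selected


def metropolis_mean(
    summaries: Iterable[WellSummary], analyte: str, scope: str = "overall"
) -> tuple[float, float]:
    """City-wide mean and sample SD of the per-well means for one analyte."""
    means = np.array([s.mean for s in _per_well_means(summaries, analyte, scope).values()])
    sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
    return float(means.mean()), sd


def area_mean(
    summaries: Iterable[WellSummary], analyte: str, area: str, scope: str = "overall"
) -> float:
    """Unweighted mean of per-well means within one land-use area (μg/L)."""
    if area not in AREAS:
        raise ValidationError(f"unknown area {area!r}")
    selected = [
        s.mean for s in _per_well_means(summaries, analyte, scope).values() if s.area == area
    ]
    if not selected:
        raise ValidationError(f"area {area!r} has no wells for analyte {analyte!r}")
    return float(np.mean(selected))


def detection_frequency(
    summaries: Iterable[WellSummary], analyte: str, scope: str = "overall"
) -> float:
    """Fraction of wells whose scope mean is above zero (i.e. ever detected)."""
    means = [s.mean for s in _per_well_means(summaries, analyte, scope).values()]
    return float(np.mean([m > 0 for m in means]))


def exceedance(
    summaries: Iterable[WellSummary],
    analyte: str,
    limit: float,
    scope: str = "overall",
    inclusive: bool = False,
) -> ExceedanceReport:
    """Count wells whose scope mean exceeds a guideline limit (μg/L).

    The comparison is strict ``>`` by default; ``inclusive=True`` uses ``>=``
    (needed e.g. for a well sitting exactly on the 40 μg/L selenium limit).
    """
    if limit <= 0:
        raise ValidationError(f"limit must be > 0, got {limit}")
    means = [s.mean for s in _per_well_means(summaries, analyte, scope).values()]
    hits = [m >= limit if inclusive else m > limit for m in means]
    return ExceedanceReport(
        analyte=analyte,
        scope=scope,
        limit=float(limit),
        inclusive=inclusive,
        n_wells=len(means),
        n_exceeding=int(np.sum(hits)),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: one input has zero variance")
    return float(stats.pearsonr(x, y).statistic)


def seasonal_pairs(
    summaries: Iterable[WellSummary], analyte: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-well (wet, dry) seasonal means, aligned by well id."""
    wet = _per_well_means(summaries, analyte, "wet")
    dry = _per_well_means(summaries, analyte, "dry")
    wells = sorted(wet, key=lambda w: (len(w), w))
    missing = set(wells) ^ set(dry)
    if missing:
        raise ValidationError(f"wells missing a seasonal mean: {sorted(missing)}")
    return (
        np.array([wet[w].mean for w in wells]),
        np.array([dry[w].mean for w in wells]),
        wells,
    )


def paired_seasonal_ttest(
    summaries: Iterable[WellSummary], analyte: str, alpha: float = 0.05
) -> SeasonalTestResult:
    """Paired two-sided t test of dry − wet per-well seasonal means.

    The same wells are monitored in both seasons, so the comparison is
    paired; df = n − 1. When the paired differences have zero spread the t
    statistic is degenerate: a zero mean difference yields t = 0, p = 1,
    otherwise p → 0 (reported as 0 with a warning).
    """
    wet, dry, wells = seasonal_pairs(summaries, analyte)
    n = len(wells)
    if n < 3:
        raise ValidationError(f"need >= 3 paired wells, got {n}")
    diff = dry - wet
    try:
        r = pearson_r(wet, dry)
    except ValidationError:
        r = float("nan")
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            t, p = 0.0, 1.0
        else:
            warnings.warn(
                f"{analyte}: paired differences are a nonzero constant; p reported as 0",
                RuntimeWarning,
                stacklevel=2,
            )
            t = float(np.inf * np.sign(diff[0]))
            p = 0.0
    else:
        res = stats.ttest_rel(dry, wet)
        t, p = float(res.statistic), float(res.pvalue)
    return SeasonalTestResult(
        analyte=analyte, statistic=t, df=n - 1, p_value=p, alpha=alpha, pearson_r=r
    )


def anova_oneway(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]):
    """Classical one-way ANOVA over ≥2 groups of ≥2 values each.

    Returns ``(F, df1, df2, p, ss_between, ss_within)``; the decomposition
    satisfies SS_between + SS_within = SS_total. All groups constant (zero
    within- and between-variance) is rejected as undefined.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_total = float(((pooled - grand) ** 2).sum())
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1 = len(arrays) - 1
    df2 = pooled.size - len(arrays)
    if ss_within == 0 and ss_between == 0:
        raise ValidationError("ANOVA undefined: all groups are identical constants")
    if ss_within == 0:
        raise ValidationError("ANOVA undefined: zero within-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return f, df1, df2, p, ss_between, ss_within
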