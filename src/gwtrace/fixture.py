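"""Packaged study fixture: per-well concentration summaries for 35 wells.

The fixture transcribes the study's published per-well tables (overall
mean/SD/range and wet/dry seasonal mean/SD for arsenic, antimony and
selenium; see ``data/PROVENANCE.md`` for transcription notes). It is the
reference input for the descriptive statistics, ordination and risk
pipeline, and the calibration source for the campaign simulator.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib.resources import files

import pandas as pd

from .datamodel import AREAS, IntegrityError, WellSummary

_DATA = files("gwtrace") / "data"

# SHA-256 of the packaged transcriptions; guards against silent edits.
_EXPECTED_SHA256 = {
    "table2_overall.csv": "a7c78983780c8f2af12655be132248a4cc0f75356f614d596db617518fc0e850",
    "table3_seasonal.csv": "3cbefb4d9b8acc28deb96507b508cf026ce8b757e461207f788e7fbf53b4ed8a",
}

# wells per land-use area, per the published tables' footnote markers
WELLS_PER_AREA = {"residential": 24, "commercial": 5, "industrial": 4, "agricultural": 2}
N_WELLS = sum(WELLS_PER_AREA.values())


@dataclass(frozen=True)
class StudyFixture:
    """Overall and seasonal per-well summaries plus the well→area map."""

    overall: tuple[WellSummary, ...]
    seasonal: tuple[WellSummary, ...]
    areas: dict[str, str]  # well_id -> land-use area

    @property
    def summaries(self) -> tuple[WellSummary, ...]:
        return self.overall + self.seasonal

    def frame(self) -> pd.DataFrame:
        """All summaries as a tidy DataFrame."""
        rows = [
            {
                "well_id": s.well_id,
                "area": s.area,
                "analyte": s.analyte,
                "scope": s.scope,
                "mean_ugL": s.mean,
                "sd_ugL": s.sd,
                "min_ugL": s.min,
                "max_ugL": s.max,
                "n": s.n,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows)


def _read_packaged(name: str, verify: bool) -> list[dict[str, str]]:
    raw = (_DATA / name).read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _EXPECTED_SHA256[name]:
            raise IntegrityError(
                f"packaged fixture {name} checksum mismatch: {digest} != {_EXPECTED_SHA256[name]}"
            )
    return list(csv.DictReader(raw.decode("utf-8").splitlines()))


def load_study_fixture(verify_checksum: bool = True) -> StudyFixture:
    """Load the packaged per-well summary tables.

    Returns 35 wells (24 residential, 5 commercial, 4 industrial,
    2 agricultural), each with one overall and two seasonal summaries per
    analyte. Overall rows carry the pooled n = 6 monthly samples; seasonal
    rows carry n = 3.
    """
    areas: dict[str, str] = {}

    overall = []
    for row in _read_packaged("table2_overall.csv", verify_checksum):
        areas[row["well_id"]] = row["area"]
        mean = float(row["mean_ugL"])
        overall.append(
            WellSummary(
                well_id=row["well_id"],
                analyte=row["analyte"],
                scope="overall",
                mean=mean,
                sd=float(row["sd_ugL"]),
                min=float(row["min_ugL"]),
                max=float(row["max_ugL"]),
                n=6,
                area=row["area"],
            )
        )

    seasonal = []
    for row in _read_packaged("table3_seasonal.csv", verify_checksum):
        seasonal.append(
            WellSummary(
                well_id=row["well_id"],
                analyte=row["analyte"],
                scope=row["season"],
                mean=float(row["mean_ugL"]),
                sd=float(row["sd_ugL"]),
                n=3,
                area=row["area"],
            )
        )

    fixture = StudyFixture(overall=tuple(overall), seasonal=tuple(seasonal), areas=areas)
    counts = {a: sum(1 for v in fixture.areas.values() if v == a) for a in AREAS}
    if counts != WELLS_PER_AREA:  # pragma: no cover - guards the packaged data
        raise IntegrityError(f"unexpected well counts per area: {counts}")
    return fixture


def default_registry_path() -> str:
    """Filesystem path of the packaged WHO limit / RfD registry YAML."""
    return str(_DATA / "registry_who.yaml")
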