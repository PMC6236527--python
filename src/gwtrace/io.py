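"""CSV input/output for monitoring records and result tables.

The monitoring-record schema is::

    well_id,area,season,month_index,analyte,conc_ugL

UTF-8, comma separated, "." decimal, header required. ``month_index`` may be
empty. A concentration cell of ``0`` or ``ND`` is a non-detect.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Any, Iterable, Sequence

from .datamodel import MonitoringRecord, SchemaError, ValidationError, iter_validated

RECORD_COLUMNS = ("well_id", "area", "season", "month_index", "analyte", "conc_ugL")
SCHEMA_VERSION = "1"


def read_records_csv(path: str | Path, schema_version: str = SCHEMA_VERSION) -> list[MonitoringRecord]:
    """Read a long-format monitoring campaign CSV.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` (with the 1-based data row number) for
    unparseable or negative concentrations and unknown category labels.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in RECORD_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
        records: list[MonitoringRecord] = []
        for row_no, row in enumerate(reader, start=1):
            cell = (row["conc_ugL"] or "").strip()
            if cell.upper() == "ND":
                conc = 0.0
            else:
                try:
                    conc = float(cell)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path} row {row_no}: concentration {cell!r} is not a number"
                    ) from exc
            if conc < 0:
                raise ValidationError(
                    f"{path} row {row_no}: negative concentration {conc}"
                )
            month_raw = (row.get("month_index") or "").strip()
            month = int(month_raw) if month_raw else None
            try:
                records.append(
                    MonitoringRecord(
                        well_id=row["well_id"].strip(),
                        area=row["area"].strip(),
                        season=row["season"].strip(),
                        analyte=row["analyte"].strip(),
                        concentration=conc,
                        nondetect=conc == 0.0,
                        month_index=month,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {row_no}: {exc}") from exc
    if not records:
        raise ValidationError(f"{path}: no data rows")
    return iter_validated(records)


def _format_value(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _rows_to_dicts(rows: Sequence[Any]) -> list[dict[str, Any]]:
    out = []
    for row in rows:
        if dataclasses.is_dataclass(row) and not isinstance(row, type):
            out.append(dataclasses.asdict(row))
        elif isinstance(row, dict):
            out.append(row)
        else:
            raise ValidationError(f"cannot serialise row of type {type(row).__name__}")
    return out


def write_table_csv(rows: Sequence[Any], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write dataclass or dict rows to CSV with a deterministic column order.

    Floats are written at full (round-trip) precision so that write → read
    is the identity. An empty row set produces a header-only file when
    ``columns`` is given, otherwise an empty file with no header.
    """
    dicts = _rows_to_dicts(rows)
    if columns is None:
        columns = list(dicts[0].keys()) if dicts else []
    else:
        columns = list(columns)
    for i, d in enumerate(dicts):
        extra = set(d) - set(columns)
        missing = set(columns) - set(d)
        if extra or missing:
            raise ValidationError(
                f"row {i} does not share the table schema "
                f"(extra={sorted(extra)}, missing={sorted(missing)})"
            )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        if columns:
            writer.writerow(columns)
        for d in dicts:
            writer.writerow([_format_value(d[c]) for c in columns])


def records_to_csv(records: Iterable[MonitoringRecord], path: str | Path) -> None:
    """Write monitoring records in the documented campaign schema."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RECORD_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.well_id,
                    rec.area,
                    rec.season,
                    "" if rec.month_index is None else rec.month_index,
                    rec.analyte,
                    _format_value(float(rec.concentration)),
                ]
            )
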