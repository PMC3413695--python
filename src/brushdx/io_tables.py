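"""Patient-level Ct table I/O and machine-readable result reports.

The interchange format is a plain CSV with one row per patient: an
identifier column, a truth-label column (``malignant``/``benign``/
``unknown``), a cytology column (the five routine-cytology read-outs plus
``missing``), and one numeric column per gene carrying the threshold
cycle (Ct).  Cells that fail to parse as numbers become explicit missing
values; the tokens ``censored`` and ``>40`` mark reactions that never
crossed the detection threshold within the 40-cycle protocol and are
encoded as Ct = 40 with a censored flag (undetectably low expression,
which is distinct from a missing measurement).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping

__all__ = [
    "MAX_CYCLES",
    "Group",
    "Cytology",
    "CtValue",
    "CtRecord",
    "TableSchema",
    "SchemaError",
    "ValidationError",
    "read_ct_table",
    "write_ct_table",
    "write_report",
    "read_report",
    "percent_field",
]

#: Total cycles of the amplification protocol; Ct values are censored here.
MAX_CYCLES = 40.0

CENSORED_TOKENS = frozenset({"censored", ">40", "undetected"})
MISSING_TOKENS = frozenset({"", "na", "nan", "n/a", "missing", "null", "none"})


class Group(str, Enum):
    MALIGNANT = "malignant"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class Cytology(str, Enum):
    POSITIVE = "positive"
    SUSPICIOUS = "suspicious"
    ATYPICAL = "atypical"
    NEGATIVE = "negative"
    INADEQUATE = "inadequate"
    MISSING = "missing"


class SchemaError(ValueError):
    """The CSV header does not match the declared schema."""


class ValidationError(ValueError):
    """A row violates the Ct-table invariants."""


@dataclass(frozen=True)
class CtValue:
    """One Ct measurement: a value in (0, 40], a censored-at-40 flag, or missing."""

    value: float | None
    censored: bool = False

    @property
    def is_missing(self) -> bool:
        return self.value is None

    def __post_init__(self) -> None:
        if self.value is not None:
            if not math.isfinite(self.value) or not 0 < self.value <= MAX_CYCLES:
                raise ValidationError(
                    f"Ct value {self.value!r} outside (0, {MAX_CYCLES:g}]"
                )
            if self.censored and self.value != MAX_CYCLES:
                raise ValidationError("censored Ct must equal the cycle limit")
        elif self.censored:
            raise ValidationError("a censored Ct carries the value 40, not missing")


MISSING_CT = CtValue(None)
CENSORED_CT = CtValue(MAX_CYCLES, censored=True)


@dataclass
class CtRecord:
    """Raw per-patient data: Ct per gene, truth label, cytology category."""

    patient_id: str
    group: Group
    cytology: Cytology
    ct: dict[str, CtValue] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return list(self.ct)


@dataclass(frozen=True)
class TableSchema:
    """Column-name mapping for a Ct CSV.

    ``gene_cols`` maps CSV column names to gene names; every column not
    named here and not one of the id/group/cytology columns is treated as
    a gene column named by its header.
    """

    patient_id_col: str = "patient_id"
    group_col: str = "group"
    cytology_col: str = "cytology"
    gene_cols: Mapping[str, str] | None = None


def _parse_ct_cell(raw: str) -> CtValue:
    token = raw.strip().lower()
    if token in MISSING_TOKENS:
        return MISSING_CT
    if token in CENSORED_TOKENS:
        return CENSORED_CT
    try:
        value = float(token)
    except ValueError:
        return MISSING_CT
    if math.isnan(value):
        return MISSING_CT
    return CtValue(value)


def _parse_enum(raw: str, enum_cls: type[Enum], row_id: str, what: str) -> Enum:
    token = raw.strip().lower()
    if token in MISSING_TOKENS:
        token = "missing" if enum_cls is Cytology else "unknown"
    try:
        return enum_cls(token)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"row {row_id!r}: unknown {what} value {raw!r} (allowed: {allowed})"
        ) from None


def read_ct_table(
    path: str | Path,
    schema: TableSchema | None = None,
    reference: str = "GAPDH",
) -> list[CtRecord]:
    """Read a patient-level Ct CSV into :class:`CtRecord` objects.

    Every data row yields exactly one record (no silent drops);
    structural problems raise instead.  Unparseable numeric cells become
    missing flags.  Group and cytology strings map case-insensitively.

    Raises
    ------
    SchemaError
        If the header lacks the reference-gene column or a schema column.
    ValidationError
        On duplicate patient ids, unknown cytology/group strings, or Ct
        values outside (0, 40].
    """
    schema = schema or TableSchema()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        header = list(reader.fieldnames)
        meta_cols = {schema.patient_id_col, schema.group_col, schema.cytology_col}
        missing_meta = meta_cols - set(header)
        if missing_meta:
            raise SchemaError(f"{path}: missing columns {sorted(missing_meta)}")
        if schema.gene_cols is not None:
            gene_map = dict(schema.gene_cols)
            absent = set(gene_map) - set(header)
            if absent:
                raise SchemaError(f"{path}: gene columns {sorted(absent)} not in header")
        else:
            gene_map = {c: c for c in header if c not in meta_cols}
        if reference not in gene_map.values():
            raise SchemaError(
                f"{path}: reference-gene column for {reference!r} not found"
            )

        records: list[CtRecord] = []
        seen: set[str] = set()
        for row in reader:
            pid = (row[schema.patient_id_col] or "").strip()
            if not pid:
                raise ValidationError(f"{path}: row with empty patient_id")
            if pid in seen:
                raise ValidationError(f"{path}: duplicate patient_id {pid!r}")
            seen.add(pid)
            group = _parse_enum(row[schema.group_col] or "", Group, pid, "group")
            cytology = _parse_enum(
                row[schema.cytology_col] or "", Cytology, pid, "cytology"
            )
            ct: dict[str, CtValue] = {}
            for col, gene in gene_map.items():
                try:
                    ct[gene] = _parse_ct_cell(row[col] or "")
                except ValidationError as exc:
                    raise ValidationError(f"row {pid!r}, gene {gene}: {exc}") from None
            records.append(CtRecord(pid, group, cytology, ct))
    return records


def write_ct_table(records: Iterable[CtRecord], path: str | Path) -> None:
    """Write records to the standard Ct CSV (inverse of :func:`read_ct_table`)."""
    records = list(records)
    genes: list[str] = []
    for rec in records:
        for g in rec.ct:
            if g not in genes:
                genes.append(g)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "group", "cytology", *genes])
        for rec in records:
            row: list[str] = [rec.patient_id, rec.group.value, rec.cytology.value]
            for g in genes:
                cv = rec.ct.get(g, MISSING_CT)
                if cv.is_missing:
                    row.append("")
                elif cv.censored:
                    row.append("censored")
                else:
                    row.append(repr(cv.value))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Result reports


def percent_field(fraction: float | None) -> dict[str, Any]:
    """Store a fraction unrounded alongside its 1-decimal percent display."""
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return {"value": None, "display": "NA"}
    # round-half-up at 1 decimal on the percent scale
    display = math.floor(fraction * 1000 + 0.5) / 10
    return {"value": float(fraction), "display": f"{display:.1f}"}


def _flatten(obj: Any, prefix: str = "") -> list[tuple[str, Any]]:
    items: list[tuple[str, Any]] = []
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            items.extend(_flatten(v, f"{prefix}{k}." if prefix else f"{k}."))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            items.extend(_flatten(v, f"{prefix}{i}."))
    else:
        items.append((prefix[:-1], obj))
    return items


def write_report(report: Mapping[str, Any], path: str | Path, format: str = "json") -> None:
    """Write a structured report as JSON (nested) or CSV (flattened key/value).

    Numeric fields round-trip at full precision (floats serialized via
    ``repr``); display rounding lives only in dedicated display fields.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, allow_nan=False) + "\n")
    elif format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["key", "value", "type"])
            for key, value in _flatten(dict(report)):
                if value is None:
                    writer.writerow([key, "", "null"])
                elif isinstance(value, bool):
                    writer.writerow([key, str(value).lower(), "bool"])
                elif isinstance(value, int):
                    writer.writerow([key, str(value), "int"])
                elif isinstance(value, float):
                    writer.writerow([key, repr(value), "float"])
                else:
                    writer.writerow([key, str(value), "str"])
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> dict[str, Any]:
    """Read back a report written by :func:`write_report`.

    The CSV variant returns the flattened key/value mapping; the JSON
    variant returns the original nested structure.
    """
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    if format == "csv":
        out: dict[str, Any] = {}
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                kind, raw = row["type"], row["value"]
                if kind == "null":
                    out[row["key"]] = None
                elif kind == "bool":
                    out[row["key"]] = raw == "true"
                elif kind == "int":
                    out[row["key"]] = int(raw)
                elif kind == "float":
                    out[row["key"]] = float(raw)
                else:
                    out[row["key"]] = raw
        return out
    raise ValueError(f"unknown report format {format!r}")
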