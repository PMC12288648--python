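"""Constructed concepts from raw EHR table rows.

Each of the nine eICU-style source tables contributes a fixed string
template: the table's display name plus its descriptive column values,
rendered as ``Source = <table>; Concept = <v1>: <v2>: ...``. Constructed
concepts are the atomic unit both the concept-selection stage and the
phenotype-description stage operate on; identity is exact, case-sensitive
string equality of the rendered text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "TableSpec",
    "TABLES",
    "TABLE_NAMES",
    "RawRecord",
    "ConstructedConcept",
    "UnsupportedTableError",
    "MalformedRecordError",
    "build_concept",
    "distinct_concepts",
    "parse_concept_text",
]


@dataclass(frozen=True)
class TableSpec:
    """One source table: display name, file stem, template columns, offset column."""

    name: str
    file_stem: str
    fields: tuple[str, ...]
    offset_col: str


#: The nine source tables and their concept templates. Field order is the
#: order values are joined with ": " in the constructed-concept text.
TABLES: dict[str, TableSpec] = {
    t.name: t
    for t in (
        TableSpec("Care Plan General", "carePlanGeneral", ("cplgroup", "cplitemvalue"), "cplitemoffset"),
        TableSpec("Infusion Drug", "infusionDrug", ("drugname",), "infusionoffset"),
        TableSpec("Medication", "medication", ("drugname",), "drugstartoffset"),
        TableSpec("Note", "note", ("notevalue", "notetext"), "noteoffset"),
        TableSpec("Nurse Care", "nurseCare", ("cellattributevalue",), "nursecareoffset"),
        TableSpec("Nurse Charting", "nurseCharting", ("nursingchartcelltypevalname", "nursingchartvalue"), "nursingchartoffset"),
        TableSpec("Respiratory Care", "respiratoryCare", ("airwaytype",), "respcarestatusoffset"),
        TableSpec("Respiratory Charting", "respiratoryCharting", ("respcharttypecat", "respchartvaluelabel", "respchartvalue"), "respchartoffset"),
        TableSpec("Treatment", "treatment", ("treatmentstring",), "treatmentoffset"),
    )
}

TABLE_NAMES: tuple[str, ...] = tuple(TABLES)


class UnsupportedTableError(ValueError):
    """Record names a table outside the nine-table set."""


class MalformedRecordError(ValueError):
    """Record is missing a template column required by its table."""


@dataclass(frozen=True)
class RawRecord:
    """One timestamped row from one of the nine source tables.

    ``offset_minutes`` is minutes relative to ICU admission and may be
    negative. ``fields`` holds the table's template column values as
    strings (possibly empty, never absent).
    """

    encounter_id: str
    table: str
    offset_minutes: int
    fields: tuple[tuple[str, str], ...]

    @staticmethod
    def make(encounter_id: str, table: str, offset_minutes: int, **fields: str) -> "RawRecord":
        if table not in TABLES:
            raise UnsupportedTableError(f"unknown source table: {table!r}")
        spec = TABLES[table]
        missing = [c for c in spec.fields if c not in fields]
        if missing:
            raise MalformedRecordError(f"{table} record missing column(s) {missing}")
        ordered = tuple((c, str(fields[c])) for c in spec.fields)
        return RawRecord(encounter_id, table, int(offset_minutes), ordered)

    def field_map(self) -> dict[str, str]:
        return dict(self.fields)


@dataclass(frozen=True)
class ConstructedConcept:
    source_table: str
    text: str = field(compare=True)

    def __post_init__(self) -> None:
        if not self.text.startswith("Source = "):
            raise ValueError("constructed-concept text must start with 'Source = '")


_LINE_BREAKS = re.compile(r"[\r\n]+")


def _clean(value: str) -> str:
    # Trailing line breaks are dropped; internal ones collapse to one space
    # so a concept always occupies a single line inside a description.
    return _LINE_BREAKS.sub(" ", value.rstrip("\r\n"))


def build_concept(record: RawRecord) -> ConstructedConcept:
    """Render a raw record into its constructed concept.

    The template is ``Source = <table>; Concept = <values joined by ': '>``
    with values taken in the table's fixed column order. Empty values are
    kept (as empty strings), so the mapping from field tuples to text is
    a bijection for line-break-free values.
    """
    if record.table not in TABLES:
        raise UnsupportedTableError(f"unknown source table: {record.table!r}")
    spec = TABLES[record.table]
    fmap = record.field_map()
    missing = [c for c in spec.fields if c not in fmap]
    if missing:
        raise MalformedRecordError(f"{record.table} record missing column(s) {missing}")
    joined = ": ".join(_clean(fmap[c]) for c in spec.fields)
    return ConstructedConcept(record.table, f"Source = {record.table}; Concept = {joined}")


def distinct_concepts(records: Iterable[RawRecord]) -> set[ConstructedConcept]:
    """The set of distinct constructed concepts across *records*.

    Order-independent and idempotent; result size never exceeds the
    record count.
    """
    return {build_concept(r) for r in records}


def parse_concept_text(text: str) -> tuple[str, dict[str, str]]:
    """Invert :func:`build_concept`: recover (table, field values) from text.

    Splits the concept body on ``": "`` into the table's column count;
    exact inversion requires that every field value but the last is free
    of ``": "``, which holds for all shipped lexicon entries.
    """
    m = re.fullmatch(r"Source = (.+?); Concept = (.*)", text, flags=re.DOTALL)
    if not m:
        raise ValueError(f"not a constructed-concept string: {text!r}")
    table, body = m.group(1), m.group(2)
    if table not in TABLES:
        raise UnsupportedTableError(f"unknown source table: {table!r}")
    spec = TABLES[table]
    parts = body.split(": ", len(spec.fields) - 1)
    if len(parts) != len(spec.fields):
        raise MalformedRecordError(
            f"{table} concept body {body!r} does not split into {len(spec.fields)} field(s)"
        )
    return table, dict(zip(spec.fields, parts))
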