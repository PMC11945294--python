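"""Bundled OMOP CDM target-model catalogue (tables and fields).

The catalogue is shipped as a flat CSV hand-derived from the CDM v5.4
specification (39 tables), so loading it requires no network access.
Field lists are complete for the clinical and health-system tables the
default mapper targets; vocabulary/era/economics tables carry their core
columns.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources

from .model import CdaRabbitError

#: CDM versions with a bundled catalogue.
AVAILABLE_VERSIONS = ("5.4",)

_DATA_FILES = {"5.4": "cdm_v5_4.csv"}


class TableCategory(str, enum.Enum):
    CLINICAL = "clinical"
    HEALTH_SYSTEM = "health_system"
    DERIVED = "derived"
    VOCABULARY = "vocabulary"
    METADATA = "metadata"
    ECONOMICS = "economics"


@dataclass(frozen=True)
class CdmField:
    name: str
    datatype: str
    required: bool


@dataclass(frozen=True)
class CdmTable:
    name: str
    category: TableCategory
    fields: tuple[CdmField, ...]

    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def has_field(self, name: str) -> bool:
        return any(f.name == name for f in self.fields)


@dataclass(frozen=True)
class CdmCatalog:
    version: str
    tables: tuple[CdmTable, ...]

    def __len__(self) -> int:
        return len(self.tables)

    def table_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tables)

    def get_table(self, name: str) -> CdmTable:
        for t in self.tables:
            if t.name == name:
                return t
        raise KeyError(name)

    def has_table(self, name: str) -> bool:
        return any(t.name == name for t in self.tables)

    def has_field(self, table: str, field_name: str) -> bool:
        return self.has_table(table) and self.get_table(table).has_field(field_name)


def load_cdm_catalog(version: str = "5.4") -> CdmCatalog:
    """Load the bundled table/field catalogue for a CDM version.

    Raises a :class:`CdaRabbitError` listing the bundled versions when the
    requested one is unknown.  Loading is pure: two loads compare equal.
    """
    if version not in _DATA_FILES:
        raise CdaRabbitError(
            f"unknown CDM version {version!r}; available: {', '.join(AVAILABLE_VERSIONS)}"
        )
    text = (
        resources.files("cdarabbit.data").joinpath(_DATA_FILES[version]).read_text()
    )
    rows = list(csv.DictReader(text.splitlines()))
    tables: list[CdmTable] = []
    current: str | None = None
    fields: list[CdmField] = []
    category = TableCategory.CLINICAL

    def flush() -> None:
        if current is not None:
            tables.append(CdmTable(name=current, category=category, fields=tuple(fields)))

    for row in rows:
        if row["table"] != current:
            flush()
            current = row["table"]
            category = TableCategory(row["category"])
            fields = []
        fields.append(
            CdmField(
                name=row["field"],
                datatype=row["datatype"],
                required=row["required"] == "true",
            )
        )
    flush()
    names = [t.name for t in tables]
    if len(names) != len(set(names)):  # catalogue CSV must be grouped by table
        raise CdaRabbitError("catalogue CSV corrupt: duplicate table blocks")
    return CdmCatalog(version=version, tables=tuple(tables))
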