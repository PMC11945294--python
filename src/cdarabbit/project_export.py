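"""Serialize a scan into an ETL-design project file plus auxiliary exports.

The scan result is presented the way a relational profiling tool would
present a database: every reachable template becomes a *source table* whose
fields are the template's flattened element paths (with datatype,
cardinality, description and binding summary), the OMOP CDM catalogue is
the *target model*, and rank-1 default suggestions become table/field arcs.
Alternative-ranked suggestions, XPath locators and the cycle report travel
in comment fields so no information is lost in the graphical tool.

Two serializations are written on every export:

* the primary ``.json.gz`` project in a GSON-style dialect modelled on the
  open-source ETL serialization of OHDSI's Rabbit-In-a-Hat / WhiteRabbit
  lineage (``source``/``target`` databases, ``tableToTableMaps``,
  ``tableMapToFieldToFieldMaps``);
* a versioned "native" JSON sidecar with the same content under a stable,
  documented schema.

Both are deterministic: fixed inputs plus a fixed injected timestamp give
byte-identical files, and export -> load -> export round-trips exactly.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from openpyxl import Workbook

from . import __version__
from .cdm_catalog import CdmCatalog
from .default_mapper import MappingSuggestion, SuggestionLevel
from .model import CdaRabbitError, TemplateDefinition, TemplateId
from .template_graph import Locator

NATIVE_FORMAT = "cdarabbit-project"
NATIVE_VERSION = "1.0"
DEFAULT_TIMESTAMP = "1970-01-01T00:00:00Z"


class ProjectFormatError(CdaRabbitError):
    """Undecodable or structurally invalid project file."""


@dataclass
class SourceField:
    name: str
    datatype: str = ""
    cardinality: str = ""
    description: str = ""
    binding_summary: str = ""


@dataclass
class SourceTable:
    name: str
    oid: str
    description: str = ""
    comment: str = ""
    fields: list[SourceField] = field(default_factory=list)


@dataclass
class Arc:
    source: str
    target: str
    comment: str = ""
    source_field: str = ""
    target_field: str = ""


@dataclass
class ProjectDocument:
    """In-memory source-model / target-model / mapping bundle."""

    source_tables: list[SourceTable] = field(default_factory=list)
    target_tables: list[dict] = field(default_factory=list)
    table_arcs: list[Arc] = field(default_factory=list)
    field_arcs: list[Arc] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)  # unknown keys, kept for round-trip

    def source_table_names(self) -> list[str]:
        return [t.name for t in self.source_tables]

    def target_table_names(self) -> list[str]:
        return [t["name"] for t in self.target_tables]

    def validate(self) -> None:
        """Check that every arc endpoint exists in its model."""
        src = {t.name: {f.name for f in t.fields} for t in self.source_tables}
        tgt = {t["name"]: {f["name"] for f in t["fields"]} for t in self.target_tables}
        for arc in self.table_arcs:
            if arc.source not in src or arc.target not in tgt:
                raise ProjectFormatError(
                    f"table arc {arc.source} -> {arc.target} has a dangling endpoint"
                )
        for arc in self.field_arcs:
            if arc.source not in src or arc.target not in tgt:
                raise ProjectFormatError(
                    f"field arc on {arc.source} -> {arc.target}: unknown table"
                )
            if arc.source_field not in src[arc.source]:
                raise ProjectFormatError(
                    f"field arc source {arc.source}.{arc.source_field} missing"
                )
            if arc.target_field not in tgt[arc.target]:
                raise ProjectFormatError(
                    f"field arc target {arc.target}.{arc.target_field} missing"
                )


def _short_hash(oid: str) -> str:
    return hashlib.sha1(oid.encode()).hexdigest()[:6]


def _binding_summary(element) -> str:
    parts = []
    for b in element.bindings:
        if b.value_set_id:
            parts.append(f"valueSet {b.value_set_id}")
        elif b.code:
            system = b.code_system_name or b.code_system_oid
            parts.append(f"code {b.code} ({system})")
    return "; ".join(parts)


def build_project(
    templates: list[TemplateDefinition],
    locators: dict[tuple[str, Optional[str]], list[Locator]],
    suggestions: list[MappingSuggestion],
    catalogue: CdmCatalog,
    root_oids: Optional[list[str]] = None,
    cycle_report_text: str = "",
    timestamp: str = DEFAULT_TIMESTAMP,
) -> ProjectDocument:
    """Assemble the in-memory project from scan outputs.

    Source table names are template display names, disambiguated with a
    short OID hash on collision; the full OID always rides in the comment.
    """
    if not templates:
        raise CdaRabbitError("nothing to export: template list is empty")

    names_seen: dict[str, int] = {}
    name_by_key: dict[tuple[str, Optional[str]], str] = {}
    source_tables = []
    for t in templates:
        name = t.display_name
        if name in names_seen:
            name = f"{name}_{_short_hash(t.id.oid)}"
        names_seen[name] = 1
        name_by_key[t.id.key] = name
        locs = locators.get(t.id.key, [])
        comment_bits = [f"templateId {t.id.oid}"]
        if t.id.effective_date:
            comment_bits.append(f"effectiveDate {t.id.effective_date}")
        comment_bits.append(f"level {t.level.value}")
        comment_bits.append(f"R-MIM class {t.rmim_class.value}")
        for loc in locs:
            comment_bits.append(f"locator {loc.absolute_path}")
        source_tables.append(
            SourceTable(
                name=name,
                oid=t.id.oid,
                description=t.description,
                comment="; ".join(comment_bits),
                fields=[
                    SourceField(
                        name=e.relative_path,
                        datatype=e.datatype,
                        cardinality=e.cardinality,
                        description=e.description,
                        binding_summary=_binding_summary(e),
                    )
                    for e in t.elements
                ],
            )
        )

    target_tables = [
        {
            "name": t.name,
            "fields": [
                {"name": f.name, "type": f.datatype, "required": f.required}
                for f in t.fields
            ],
        }
        for t in catalogue.tables
    ]

    by_template = {t.id.key: t for t in templates}
    table_arcs: list[Arc] = []
    field_arcs: list[Arc] = []
    rank1_tables: set[tuple[tuple[str, Optional[str]], str]] = set()
    for s in suggestions:
        if s.source_template.key not in by_template:
            continue
        if s.level is SuggestionLevel.TABLE and s.rank == 1:
            rank1_tables.add((s.source_template.key, s.target_table))
    for s in suggestions:
        key = s.source_template.key
        if key not in by_template:
            continue
        src_name = name_by_key[key]
        if s.level is SuggestionLevel.TABLE:
            if s.rank == 1:
                alternatives = [
                    a.target_table
                    for a in suggestions
                    if a.level is SuggestionLevel.TABLE
                    and a.source_template.key == key
                    and a.rank > 1
                ]
                comment = f"default mapping ({s.rationale.value})"
                if alternatives:
                    comment += "; alternatives: " + ", ".join(
                        f"{t} (rank {i + 2})" for i, t in enumerate(alternatives)
                    )
                table_arcs.append(Arc(source=src_name, target=s.target_table, comment=comment))
        else:
            if (key, s.target_table) in rank1_tables and s.rank == 1:
                field_arcs.append(
                    Arc(
                        source=src_name,
                        target=s.target_table,
                        source_field=s.source_element_path,
                        target_field=s.target_field,
                        comment=f"default mapping ({s.rationale.value})",
                    )
                )

    doc = ProjectDocument(
        source_tables=source_tables,
        target_tables=target_tables,
        table_arcs=table_arcs,
        field_arcs=field_arcs,
        metadata={
            "tool": "cdarabbit",
            "toolVersion": __version__,
            "created": timestamp,
            "cdmVersion": catalogue.version,
            "rootOids": root_oids or [],
            "cycleReport": cycle_report_text,
        },
    )
    doc.validate()
    return doc


# -- serialization ---------------------------------------------------------


def _to_dialect_dict(doc: ProjectDocument) -> dict:
    field_maps = []
    pairs = []
    for arc in doc.table_arcs:
        pairs.append((arc.source, arc.target))
    for arc in doc.field_arcs:
        if (arc.source, arc.target) not in pairs:
            pairs.append((arc.source, arc.target))
    for src, tgt in pairs:
        fields = [
            {
                "sourceField": a.source_field,
                "targetField": a.target_field,
                "comment": a.comment,
            }
            for a in doc.field_arcs
            if a.source == src and a.target == tgt
        ]
        field_maps.append({"sourceTable": src, "targetTable": tgt, "fields": fields})
    out = {
        "source": {
            "name": "CDA Templates",
            "tables": [
                {
                    "name": t.name,
                    "oid": t.oid,
                    "description": t.description,
                    "comment": t.comment,
                    "rowCount": 0,
                    "rowsCheckedCount": 0,
                    "fields": [
                        {
                            "name": f.name,
                            "type": f.datatype,
                            "cardinality": f.cardinality,
                            "description": f.description,
                            "binding": f.binding_summary,
                            "valueCounts": [],
                            "fractionEmpty": 0.0,
                        }
                        for f in t.fields
                    ],
                }
                for t in doc.source_tables
            ],
        },
        "target": {"name": f"OMOP CDM v{doc.metadata.get('cdmVersion', '')}",
                   "tables": doc.target_tables},
        "tableToTableMaps": [
            {
                "sourceTable": a.source,
                "targetTable": a.target,
                "comment": a.comment,
                "logic": "",
            }
            for a in doc.table_arcs
        ],
        "tableMapToFieldToFieldMaps": field_maps,
        "metadata": doc.metadata,
    }
    out.update(doc.extras)
    return out


_KNOWN_KEYS = {
    "source",
    "target",
    "tableToTableMaps",
    "tableMapToFieldToFieldMaps",
    "metadata",
}


def _from_dialect_dict(data: dict) -> ProjectDocument:
    try:
        source_tables = [
            SourceTable(
                name=t["name"],
                oid=t.get("oid", ""),
                description=t.get("description", ""),
                comment=t.get("comment", ""),
                fields=[
                    SourceField(
                        name=f["name"],
                        datatype=f.get("type", ""),
                        cardinality=f.get("cardinality", ""),
                        description=f.get("description", ""),
                        binding_summary=f.get("binding", ""),
                    )
                    for f in t.get("fields", [])
                ],
            )
            for t in data["source"]["tables"]
        ]
        target_tables = data["target"]["tables"]
        table_arcs = [
            Arc(
                source=m["sourceTable"],
                target=m["targetTable"],
                comment=m.get("comment", ""),
            )
            for m in data.get("tableToTableMaps", [])
        ]
        field_arcs = []
        for fmap in data.get("tableMapToFieldToFieldMaps", []):
            for f in fmap.get("fields", []):
                field_arcs.append(
                    Arc(
                        source=fmap["sourceTable"],
                        target=fmap["targetTable"],
                        source_field=f.get("sourceField", ""),
                        target_field=f.get("targetField", ""),
                        comment=f.get("comment", ""),
                    )
                )
    except (KeyError, TypeError) as exc:
        raise ProjectFormatError(f"project file structure invalid: {exc}") from exc
    extras = {k: v for k, v in data.items() if k not in _KNOWN_KEYS}
    return ProjectDocument(
        source_tables=source_tables,
        target_tables=target_tables,
        table_arcs=table_arcs,
        field_arcs=field_arcs,
        metadata=data.get("metadata", {}),
        extras=extras,
    )


def _to_native_dict(doc: ProjectDocument) -> dict:
    return {
        "format": NATIVE_FORMAT,
        "formatVersion": NATIVE_VERSION,
        "project": _to_dialect_dict(doc),
    }


def _json_bytes(data: dict) -> bytes:
    return (json.dumps(data, indent=2, ensure_ascii=False) + "\n").encode("utf-8")


def native_sidecar_path(destination: str | os.PathLike) -> Path:
    dest = Path(destination)
    name = dest.name
    if name.endswith(".json.gz"):
        return dest.with_name(name[: -len(".json.gz")] + ".native.json")
    return dest.with_name(name + ".native.json")


def export_project(
    templates: list[TemplateDefinition],
    locators: dict,
    suggestions: list[MappingSuggestion],
    catalogue: CdmCatalog,
    destination: str | os.PathLike,
    root_oids: Optional[list[str]] = None,
    cycle_report_text: str = "",
    timestamp: str = DEFAULT_TIMESTAMP,
) -> ProjectDocument:
    """Write the compressed project file (and native sidecar); return the
    in-memory document.  Raises on an empty template list or unwritable
    destination."""
    doc = build_project(
        templates,
        locators,
        suggestions,
        catalogue,
        root_oids=root_oids,
        cycle_report_text=cycle_report_text,
        timestamp=timestamp,
    )
    write_project(doc, destination)
    return doc


def write_project(doc: ProjectDocument, destination: str | os.PathLike) -> None:
    doc.validate()
    payload = _json_bytes(_to_dialect_dict(doc))
    dest = Path(destination)
    try:
        # mtime zeroed and FNAME suppressed so identical content gives
        # identical bytes regardless of destination name or wall clock
        with open(dest, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, filename="") as gz:
                gz.write(payload)
        native_sidecar_path(dest).write_bytes(_json_bytes(_to_native_dict(doc)))
    except OSError as exc:
        raise CdaRabbitError(f"cannot write project to {dest}: {exc}") from exc


def load_project(source: str | os.PathLike) -> ProjectDocument:
    """Read a project file written by :func:`export_project` (gzip or plain
    JSON, dialect or native).  Unknown keys are preserved opaquely so a
    re-export reproduces them."""
    path = Path(source)
    try:
        blob = path.read_bytes()
    except OSError as exc:
        raise ProjectFormatError(f"cannot read {path}: {exc}") from exc
    if blob[:2] == b"\x1f\x8b":
        try:
            blob = gzip.decompress(blob)
        except (OSError, EOFError) as exc:
            raise ProjectFormatError(f"{path}: truncated or corrupt gzip") from exc
    try:
        data = json.loads(blob.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ProjectFormatError(f"{path}: not a JSON project file: {exc}") from exc
    if not isinstance(data, dict):
        raise ProjectFormatError(f"{path}: unexpected JSON payload")
    if data.get("format") == NATIVE_FORMAT:
        data = data.get("project", {})
    return _from_dialect_dict(data)


# -- scan report -----------------------------------------------------------

SCAN_REPORT_COLUMNS = (
    "Table",
    "Field",
    "Description",
    "Type",
    "Cardinality",
    "Binding",
    "N rows",
    "N rows checked",
    "Fraction empty",
)


def export_scan_report(
    templates: list[TemplateDefinition],
    locators: dict,
    destination: str | os.PathLike,
) -> None:
    """Write a WhiteRabbit-style scan workbook.

    One overview row per (template, element); instance-statistics columns
    are zero because no instance data is profiled.  A template without
    elements is still listed (single row, empty field).
    """
    if not templates:
        raise CdaRabbitError("nothing to export: template list is empty")
    wb = Workbook()
    ws = wb.active
    ws.title = "Overview"
    ws.append(list(SCAN_REPORT_COLUMNS))
    for t in templates:
        if not t.elements:
            ws.append([t.display_name, "", t.description, "", "", "", 0, 0, 0.0])
            continue
        for e in t.elements:
            ws.append(
                [
                    t.display_name,
                    e.relative_path,
                    e.description,
                    e.datatype,
                    e.cardinality,
                    _binding_summary(e),
                    0,
                    0,
                    0.0,
                ]
            )
    ws2 = wb.create_sheet("Locators")
    ws2.append(["Template", "OID", "Locator", "Depth"])
    for t in templates:
        for loc in locators.get(t.id.key, []):
            ws2.append([t.display_name, t.id.oid, loc.absolute_path, loc.depth])
    try:
        wb.save(destination)
    except OSError as exc:
        raise CdaRabbitError(f"cannot write scan report: {exc}") from exc
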