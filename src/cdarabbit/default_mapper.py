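"""Default CDM mapping suggestions from CDA R-MIM class semantics.

The R-MIM class a template constrains carries enough meaning to propose a
first mapping target before any instance data exists: a template
constraining the *Patient* class will land in the CDM ``person`` table and
its ``administrativeGenderCode`` element in ``person.gender_source_value``;
an *Observation* entry most likely feeds ``measurement`` (with
``observation`` as the ranked alternative); a *Supply* or
*SubstanceAdministration* entry feeds ``drug_exposure``.  The bundled rule
table is a reconstruction of that class-to-table semantics, shipped as an
editable CSV so deployments can override or extend it.

An optional refinement uses terminology bindings: a code system whose codes
all live in one OMOP domain (ATC -> drug, LOINC -> measurement) pins the
matching table suggestion to rank 1.

This module also inventories the source vocabularies (value sets and code
systems) referenced across templates -- the input a terminology-mapping
step such as Usagi needs.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from fnmatch import fnmatchcase
from importlib import resources
from typing import Iterable, Optional

from .cdm_catalog import CdmCatalog
from .model import (
    BindingKind,
    CdaRabbitError,
    RmimClass,
    TemplateDefinition,
    TemplateId,
)


class SuggestionLevel(str, enum.Enum):
    TABLE = "table"
    FIELD = "field"


class Rationale(str, enum.Enum):
    RMIM_DEFAULT = "rmim_default"
    VOCABULARY_DOMAIN = "vocabulary_domain"
    MANUAL = "manual"


@dataclass(frozen=True)
class MappingSuggestion:
    """A suggested arc from a template (element) to a CDM table (field)."""

    level: SuggestionLevel
    source_template: TemplateId
    source_element_path: str
    target_table: str
    target_field: str
    rationale: Rationale
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.level is SuggestionLevel.TABLE and self.target_field:
            raise ValueError("table-level suggestion carries no target_field")


@dataclass(frozen=True)
class DefaultMappingRule:
    """One class->table rule with its element-pattern field rules.

    ``field_rules`` are (glob over hl7-prefixed relative paths, CDM field)
    pairs, checked in order; the first matching pattern wins per element.
    """

    rmim_class: RmimClass
    target_table: str
    rank: int
    field_rules: tuple[tuple[str, str], ...] = ()


@dataclass
class VocabularyInventoryEntry:
    """One distinct source vocabulary (value set or code system) in use."""

    key: str
    kind: BindingKind
    display: str
    uses: list[tuple[TemplateId, str]] = field(default_factory=list)

    @property
    def usage_count(self) -> int:
        return len(self.uses)


def load_default_rules(
    catalogue: CdmCatalog, source: Optional[str] = None
) -> list[DefaultMappingRule]:
    """Load the rule table (bundled CSV by default) and validate every
    target against the catalogue; an unknown table/field is a configuration
    error here, not later at suggestion time."""
    if source is None:
        text = (
            resources.files("cdarabbit.data")
            .joinpath("default_mappings.csv")
            .read_text()
        )
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    grouped: dict[tuple[str, str, int], list[tuple[str, str]]] = {}
    order: list[tuple[str, str, int]] = []
    for row in csv.DictReader(text.splitlines()):
        key = (row["rmim_class"], row["target_table"], int(row["rank"]))
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        if row["element_pattern"]:
            grouped[key].append((row["element_pattern"], row["target_field"]))

    rules = []
    for cls_name, table, rank in order:
        try:
            cls = RmimClass(cls_name)
        except ValueError as exc:
            raise CdaRabbitError(f"rule table: unknown R-MIM class {cls_name!r}") from exc
        if not catalogue.has_table(table):
            raise CdaRabbitError(
                f"rule table: target table {table!r} not in CDM {catalogue.version}"
            )
        for pattern, field_name in grouped[(cls_name, table, rank)]:
            if not catalogue.has_field(table, field_name):
                raise CdaRabbitError(
                    f"rule table: {table}.{field_name} not in CDM {catalogue.version}"
                    f" (pattern {pattern!r})"
                )
        rules.append(
            DefaultMappingRule(
                rmim_class=cls,
                target_table=table,
                rank=rank,
                field_rules=tuple(grouped[(cls_name, table, rank)]),
            )
        )
    return rules


def load_code_system_domains(source: Optional[str] = None) -> dict[str, str]:
    """Map code-system/value-set identifiers to their single OMOP domain table.

    Only unambiguous systems are bundled (ATC, LOINC, ICD-10); everything
    else stays unmapped.
    """
    if source is None:
        text = (
            resources.files("cdarabbit.data")
            .joinpath("code_system_domains.csv")
            .read_text()
        )
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    return {row["key"]: row["target_table"] for row in csv.DictReader(text.splitlines())}


def suggest_table_mappings(
    template: TemplateDefinition, rules: Iterable[DefaultMappingRule]
) -> list[MappingSuggestion]:
    """Table-level suggestions for a template, ordered by rank.

    A pure function of (rmim_class, rules); templates with an unresolved
    class yield nothing.
    """
    if template.rmim_class is RmimClass.UNKNOWN:
        return []
    hits = [r for r in rules if r.rmim_class is template.rmim_class]
    hits.sort(key=lambda r: r.rank)
    return [
        MappingSuggestion(
            level=SuggestionLevel.TABLE,
            source_template=template.id,
            source_element_path="",
            target_table=r.target_table,
            target_field="",
            rationale=Rationale.RMIM_DEFAULT,
            rank=r.rank,
        )
        for r in hits
    ]


def suggest_field_mappings(
    template: TemplateDefinition,
    table_suggestion: MappingSuggestion,
    rules: Iterable[DefaultMappingRule],
) -> list[MappingSuggestion]:
    """Field-level suggestions into the table a table-level suggestion chose.

    Elements are checked in document order against the fired rule's
    patterns; an element matching nothing yields nothing.
    """
    if table_suggestion.level is not SuggestionLevel.TABLE:
        raise CdaRabbitError("field mapping needs a table-level parent suggestion")
    rule = next(
        (
            r
            for r in rules
            if r.rmim_class is template.rmim_class
            and r.target_table == table_suggestion.target_table
            and r.rank == table_suggestion.rank
        ),
        None,
    )
    if rule is None:
        return []
    out = []
    for element in template.elements:
        for pattern, field_name in rule.field_rules:
            if fnmatchcase(element.relative_path, pattern):
                out.append(
                    MappingSuggestion(
                        level=SuggestionLevel.FIELD,
                        source_template=template.id,
                        source_element_path=element.relative_path,
                        target_table=rule.target_table,
                        target_field=field_name,
                        rationale=table_suggestion.rationale,
                        rank=table_suggestion.rank,
                    )
                )
                break
    return out


def suggest_all(
    templates: Iterable[TemplateDefinition],
    rules: Iterable[DefaultMappingRule],
) -> list[MappingSuggestion]:
    """Table- and field-level suggestions for a whole scan, element order
    preserved; field suggestions always follow their table-level parent."""
    rules = list(rules)
    out: list[MappingSuggestion] = []
    for template in templates:
        for table_sugg in suggest_table_mappings(template, rules):
            out.append(table_sugg)
            out.extend(suggest_field_mappings(template, table_sugg, rules))
    return out


def refine_by_vocabulary(
    template: TemplateDefinition,
    suggestions: list[MappingSuggestion],
    domain_table: Optional[dict[str, str]] = None,
) -> list[MappingSuggestion]:
    """Re-rank (or add) table suggestions using vocabulary-domain routing.

    If any element binding resolves through ``domain_table`` -- by code
    system OID, code system name, or value set id -- the suggestion for
    that table is promoted to rank 1 with rationale ``vocabulary_domain``
    (or appended if absent).  Existing suggestions are never removed, so
    the suggestion count never decreases.
    """
    if domain_table is None:
        domain_table = load_code_system_domains()
    routed: list[str] = []
    for element in template.elements:
        for binding in element.bindings:
            for probe in (
                binding.code_system_oid,
                binding.code_system_name,
                binding.value_set_id,
            ):
                if probe and probe in domain_table:
                    table = domain_table[probe]
                    if table not in routed:
                        routed.append(table)
                    break
    if not routed:
        return list(suggestions)

    mine = [
        s
        for s in suggestions
        if s.level is SuggestionLevel.TABLE and s.source_template == template.id
    ]
    others = [s for s in suggestions if s not in mine]
    promoted_tables = [t for t in routed if any(s.target_table == t for s in mine)]
    appended = [
        MappingSuggestion(
            level=SuggestionLevel.TABLE,
            source_template=template.id,
            source_element_path="",
            target_table=t,
            target_field="",
            rationale=Rationale.VOCABULARY_DOMAIN,
            rank=1,
        )
        for t in routed
        if not any(s.target_table == t for s in mine)
    ]
    reranked: list[MappingSuggestion] = []
    rank = len(appended)
    promoted = [s for s in mine if s.target_table in promoted_tables]
    demoted = [s for s in mine if s.target_table not in promoted_tables]
    for s in sorted(promoted, key=lambda s: s.rank):
        rank += 1
        reranked.append(replace(s, rank=rank, rationale=Rationale.VOCABULARY_DOMAIN))
    for s in sorted(demoted, key=lambda s: s.rank):
        rank += 1
        reranked.append(replace(s, rank=rank))
    # field-level suggestions keep their original rank linkage by table
    return appended + reranked + others


def collect_vocabulary_inventory(
    templates: Iterable[TemplateDefinition],
) -> list[VocabularyInventoryEntry]:
    """One entry per distinct value set / code system across all bindings,
    with usage counts and use sites, sorted by usage descending then key."""
    entries: dict[str, VocabularyInventoryEntry] = {}
    for template in templates:
        for element in template.elements:
            for binding in element.bindings:
                key = binding.inventory_key
                entry = entries.get(key)
                if entry is None:
                    display = (
                        binding.code_system_name
                        or binding.value_set_id
                        or binding.code_system_oid
                        or key
                    )
                    entry = VocabularyInventoryEntry(
                        key=key, kind=binding.kind, display=display
                    )
                    entries[key] = entry
                entry.uses.append((template.id, element.relative_path))
    return sorted(entries.values(), key=lambda e: (-e.usage_count, e.key))


def inventory_csv_rows(
    inventory: Iterable[VocabularyInventoryEntry],
) -> list[tuple[str, str, int]]:
    """(source_code, source_vocabulary, frequency) rows shaped for Usagi intake."""
    return [(e.key, e.display, e.usage_count) for e in inventory]


def validate_suggestions(
    suggestions: Iterable[MappingSuggestion], catalogue: CdmCatalog
) -> None:
    """Raise if any suggestion points outside the catalogue or a field-level
    suggestion appears without its table-level parent."""
    suggestions = list(suggestions)
    table_pairs = {
        (s.source_template.key, s.target_table)
        for s in suggestions
        if s.level is SuggestionLevel.TABLE
    }
    for s in suggestions:
        if not catalogue.has_table(s.target_table):
            raise CdaRabbitError(f"suggestion targets unknown table {s.target_table!r}")
        if s.level is SuggestionLevel.FIELD:
            if not catalogue.has_field(s.target_table, s.target_field):
                raise CdaRabbitError(
                    f"suggestion targets unknown field "
                    f"{s.target_table}.{s.target_field}"
                )
            if (s.source_template.key, s.target_table) not in table_pairs:
                raise CdaRabbitError(
                    f"field suggestion {s.source_element_path} -> "
                    f"{s.target_table}.{s.target_field} lacks a table-level parent"
                )
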