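"""Domain model for HL7 CDA Template repositories.

A CDA Template is a named, OID-identified set of constraints on the CDA
R-MIM (the generic clinical-document data model of HL7 V3).  Templates are
defined at four levels -- document, header, section, entry -- and reference
each other: a document template *contains* section templates, sections
*contain* entries, and any template may *include* another that constrains
the same context node.  These types carry everything the downstream stages
(dependency graph, XPath locators, default CDM mapping, project export)
need, independent of the XML serialization they were parsed from.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

#: Namespace URI every ``hl7:`` prefixed path refers to.
HL7_NS = "urn:hl7-org:v3"
#: Conventional extension namespace kept under its own prefix.
SDTC_NS = "urn:hl7-org:sdtc"

#: XPath namespace map to use when evaluating stored paths.
NSMAP = {"hl7": HL7_NS, "sdtc": SDTC_NS}

#: Sentinel for an unbounded maximum cardinality ("*" in the source XML).
UNBOUNDED = -1

_OID_RE = re.compile(r"^\d+(\.\d+)+$")


class Status(str, enum.Enum):
    ACTIVE = "active"
    DRAFT = "draft"
    RETIRED = "retired"
    PENDING = "pending"
    OTHER = "other"


class TemplateLevel(str, enum.Enum):
    DOCUMENT = "document"
    HEADER = "header"
    SECTION = "section"
    ENTRY = "entry"
    UNSPECIFIED = "unspecified"


class RmimClass(str, enum.Enum):
    """CDA R-MIM backbone classes carrying mapping semantics."""

    CLINICAL_DOCUMENT = "ClinicalDocument"
    SECTION = "Section"
    OBSERVATION = "Observation"
    OBSERVATION_MEDIA = "ObservationMedia"
    ACT = "Act"
    ENCOUNTER = "Encounter"
    PROCEDURE = "Procedure"
    SUBSTANCE_ADMINISTRATION = "SubstanceAdministration"
    SUPPLY = "Supply"
    ORGANIZER = "Organizer"
    REGION_OF_INTEREST = "RegionOfInterest"
    PATIENT = "Patient"
    PATIENT_ROLE = "PatientRole"
    ASSIGNED_ENTITY = "AssignedEntity"
    PERSON = "Person"
    ORGANIZATION = "Organization"
    SPECIMEN = "Specimen"
    PARTICIPANT_ROLE = "ParticipantRole"
    UNKNOWN = "Unknown"


class Conformance(str, enum.Enum):
    MANDATORY = "mandatory"
    REQUIRED = "required"
    OPTIONAL = "optional"
    CONDITIONAL = "conditional"
    NOT_PERMITTED = "not_permitted"


class BindingKind(str, enum.Enum):
    VALUE_SET = "value_set"
    FIXED_CODE = "fixed_code"


class BindingStrength(str, enum.Enum):
    REQUIRED = "required"
    EXTENSIBLE = "extensible"
    PREFERRED = "preferred"
    EXAMPLE = "example"
    UNSPECIFIED = "unspecified"


class ReferenceKind(str, enum.Enum):
    INCLUDE = "include"
    CONTAINS = "contains"
    SPECIALIZES = "specializes"


class CdaRabbitError(Exception):
    """Base class for all errors raised by this package."""


@dataclass(frozen=True)
class TemplateId:
    """OID identity of a template, optionally versioned by effective date.

    Two definitions with the same ``oid`` but different ``effective_date``
    are distinct versions of one template.  ``display_name`` is carried for
    presentation only and never takes part in equality.
    """

    oid: str
    effective_date: Optional[str] = None
    display_name: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not _OID_RE.match(self.oid):
            raise ValueError(f"not a dotted-integer OID: {self.oid!r}")

    @property
    def key(self) -> tuple[str, Optional[str]]:
        return (self.oid, self.effective_date)

    def matches(self, other: "TemplateId") -> bool:
        """Version-tolerant identity: dates compare only when both are set."""
        if self.oid != other.oid:
            return False
        if self.effective_date is None or other.effective_date is None:
            return True
        return self.effective_date == other.effective_date

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.effective_date:
            return f"{self.oid}@{self.effective_date}"
        return self.oid


@dataclass(frozen=True)
class VocabularyBinding:
    """Terminology constraint on a coded element.

    Either a binding to a value set (subset of a code system, identified by
    its own OID) or a fixed single code from a named code system.
    """

    kind: BindingKind
    value_set_id: Optional[str] = None
    code: Optional[str] = None
    code_system_oid: Optional[str] = None
    code_system_name: Optional[str] = None
    strength: BindingStrength = BindingStrength.UNSPECIFIED

    def __post_init__(self) -> None:
        if self.kind is BindingKind.VALUE_SET and not self.value_set_id:
            raise ValueError("value_set binding requires value_set_id")
        if self.kind is BindingKind.FIXED_CODE and not (
            self.code and self.code_system_oid
        ):
            raise ValueError("fixed_code binding requires code and code_system_oid")

    @property
    def inventory_key(self) -> str:
        """Key under which this binding is counted in the vocabulary inventory."""
        if self.kind is BindingKind.VALUE_SET:
            return self.value_set_id  # type: ignore[return-value]
        return self.code_system_oid  # type: ignore[return-value]


@dataclass(frozen=True)
class TemplateReference:
    """Arc from one template to another.

    ``include`` constrains the same context node (empty ``via_path``),
    ``contains`` places the target template at a relative path below the
    source template's root, and ``specializes`` records R-MIM/prototype
    lineage only (no containment, no cardinality).
    """

    kind: ReferenceKind
    target: TemplateId
    via_path: str = ""
    min_occurs: int = 0
    max_occurs: int = 1

    def __post_init__(self) -> None:
        if self.kind is ReferenceKind.SPECIALIZES and self.via_path:
            raise ValueError("specializes reference carries no via_path")
        if self.max_occurs != UNBOUNDED and self.max_occurs < self.min_occurs:
            raise ValueError("max_occurs below min_occurs")


@dataclass
class TemplateElement:
    """One constrained CDA element, addressed relative to the template root."""

    relative_path: str
    description: str = ""
    datatype: str = ""
    min_occurs: int = 0
    max_occurs: int = 1
    conformance: Conformance = Conformance.OPTIONAL
    bindings: list[VocabularyBinding] = field(default_factory=list)
    contains_ref: Optional[TemplateId] = None
    fixed_attributes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.max_occurs != UNBOUNDED and self.max_occurs < self.min_occurs:
            raise ValueError(
                f"max_occurs {self.max_occurs} < min_occurs {self.min_occurs}"
                f" on {self.relative_path}"
            )

    @property
    def cardinality(self) -> str:
        hi = "*" if self.max_occurs == UNBOUNDED else str(self.max_occurs)
        return f"{self.min_occurs}..{hi}"


@dataclass
class TemplateDefinition:
    """A parsed CDA Template: metadata, constrained elements, references."""

    id: TemplateId
    status: Status = Status.OTHER
    level: TemplateLevel = TemplateLevel.UNSPECIFIED
    rmim_class: RmimClass = RmimClass.UNKNOWN
    description: str = ""
    root_element_name: str = ""
    elements: list[TemplateElement] = field(default_factory=list)
    references: list[TemplateReference] = field(default_factory=list)

    @property
    def display_name(self) -> str:
        return self.id.display_name or self.id.oid

    def containment_references(self) -> list[TemplateReference]:
        """The include/contains references (graph edges; lineage excluded)."""
        return [
            r
            for r in self.references
            if r.kind in (ReferenceKind.INCLUDE, ReferenceKind.CONTAINS)
        ]

    def specializes(self) -> list[TemplateReference]:
        return [r for r in self.references if r.kind is ReferenceKind.SPECIALIZES]


@dataclass
class TemplateRepository:
    """Collection of template definitions keyed by (oid, effective_date)."""

    templates: dict[tuple[str, Optional[str]], TemplateDefinition] = field(
        default_factory=dict
    )
    source_uri: str = ""
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self) -> Iterator[TemplateDefinition]:
        return iter(self.templates.values())

    def __contains__(self, tid: TemplateId) -> bool:
        return self.get(tid) is not None

    def add(self, template: TemplateDefinition, strict: bool = False) -> None:
        key = template.id.key
        if key in self.templates:
            if strict:
                raise CdaRabbitError(
                    f"duplicate template {template.id} (strict mode)"
                )
            self.warnings.append(
                f"duplicate template {template.id}: last definition wins"
            )
        self.templates[key] = template

    def versions(self, oid: str) -> list[TemplateDefinition]:
        return [t for k, t in self.templates.items() if k[0] == oid]

    def get(
        self, tid: TemplateId, prefer_active: bool = True
    ) -> Optional[TemplateDefinition]:
        """Resolve a reference target to a definition.

        An exact (oid, effective_date) hit wins.  A date-less reference to a
        multi-version oid picks, by default, the active version with the
        latest effective date, falling back to the latest overall.
        """
        exact = self.templates.get(tid.key)
        if exact is not None:
            return exact
        candidates = self.versions(tid.oid)
        if tid.effective_date is not None:
            candidates = [
                t for t in candidates if t.id.effective_date in (None, tid.effective_date)
            ]
        if not candidates:
            return None
        if len(candidates) == 1:
            return candidates[0]

        def date_key(t: TemplateDefinition) -> str:
            return t.id.effective_date or ""

        if prefer_active:
            active = [t for t in candidates if t.status is Status.ACTIVE]
            if active:
                return max(active, key=date_key)
        return max(candidates, key=date_key)
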