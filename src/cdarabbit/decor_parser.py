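"""Parser for template repositories in the ART-DECOR "decor" XML dialect.

A decor file carries template definitions as ``<template>`` children of a
``<rules>`` element (the element may sit directly at the root or be nested
under a project wrapper).  The subset read here:

* cardinalities from ``minimumMultiplicity`` / ``maximumMultiplicity``
  (``"*"`` meaning unbounded),
* conformance from ``@conformance`` / ``@isMandatory``,
* R-MIM/prototype lineage from ``<relationship type="SPEC" template=...>``,
* containment from ``element/@contains`` and root-level ``<include ref=...>``,
* template level from ``<classification type="cda...level"/>``,
* vocabulary bindings from ``<vocabulary>`` children of an element,
* fixed attribute values from ``<attribute name=... value=...>``.

All stored element paths are normalized to the canonical ``hl7:`` prefix for
``urn:hl7-org:v3`` regardless of the prefixes used in the source file, so
locator strings are stable and comparable across files.  Extension
namespaces (sdtc) keep their conventional prefix.
"""

from __future__ import annotations

import io
import os
from typing import IO, Optional, Union

from lxml import etree

from .model import (
    HL7_NS,
    SDTC_NS,
    UNBOUNDED,
    BindingKind,
    BindingStrength,
    CdaRabbitError,
    Conformance,
    ReferenceKind,
    RmimClass,
    Status,
    TemplateDefinition,
    TemplateElement,
    TemplateId,
    TemplateLevel,
    TemplateReference,
    TemplateRepository,
    VocabularyBinding,
)

Source = Union[str, os.PathLike, bytes, IO[bytes]]


class RepositoryParseError(CdaRabbitError):
    """Malformed XML or structural problems in a decor file."""


class NotATemplateRepositoryError(RepositoryParseError):
    """Well-formed XML without a ``<rules>`` element."""


_LEVEL_BY_CLASSIFICATION = {
    "cdadocumentlevel": TemplateLevel.DOCUMENT,
    "cdaheaderlevel": TemplateLevel.HEADER,
    "cdasectionlevel": TemplateLevel.SECTION,
    "cdaentrylevel": TemplateLevel.ENTRY,
}

_STATUS_MAP = {
    "active": Status.ACTIVE,
    "final": Status.ACTIVE,
    "draft": Status.DRAFT,
    "retired": Status.RETIRED,
    "deprecated": Status.RETIRED,
    "pending": Status.PENDING,
    "review": Status.PENDING,
}

_CONFORMANCE_MAP = {
    "R": Conformance.REQUIRED,
    "O": Conformance.OPTIONAL,
    "C": Conformance.CONDITIONAL,
    "NP": Conformance.NOT_PERMITTED,
}

_STRENGTH_MAP = {
    "required": BindingStrength.REQUIRED,
    "extensible": BindingStrength.EXTENSIBLE,
    "preferred": BindingStrength.PREFERRED,
    "example": BindingStrength.EXAMPLE,
}

#: Fallback table from the element name a template constrains to the CDA
#: R-MIM class of that element, used when no prototype lineage is declared.
ELEMENT_NAME_CLASS_TABLE: dict[str, RmimClass] = {
    "hl7:ClinicalDocument": RmimClass.CLINICAL_DOCUMENT,
    "hl7:section": RmimClass.SECTION,
    "hl7:observation": RmimClass.OBSERVATION,
    "hl7:observationMedia": RmimClass.OBSERVATION_MEDIA,
    "hl7:act": RmimClass.ACT,
    "hl7:encounter": RmimClass.ENCOUNTER,
    "hl7:encompassingEncounter": RmimClass.ENCOUNTER,
    "hl7:procedure": RmimClass.PROCEDURE,
    "hl7:substanceAdministration": RmimClass.SUBSTANCE_ADMINISTRATION,
    "hl7:supply": RmimClass.SUPPLY,
    "hl7:organizer": RmimClass.ORGANIZER,
    "hl7:regionOfInterest": RmimClass.REGION_OF_INTEREST,
    "hl7:patient": RmimClass.PATIENT,
    "hl7:patientRole": RmimClass.PATIENT_ROLE,
    "hl7:assignedEntity": RmimClass.ASSIGNED_ENTITY,
    "hl7:assignedAuthor": RmimClass.ASSIGNED_ENTITY,
    "hl7:person": RmimClass.PERSON,
    "hl7:assignedPerson": RmimClass.PERSON,
    "hl7:organization": RmimClass.ORGANIZATION,
    "hl7:representedCustodianOrganization": RmimClass.ORGANIZATION,
    "hl7:specimen": RmimClass.SPECIMEN,
    "hl7:specimenRole": RmimClass.SPECIMEN,
    "hl7:participantRole": RmimClass.PARTICIPANT_ROLE,
}

# Reconstructed map of the CDA structural prototype template family
# (2.16.840.1.113883.10.12.*) to R-MIM classes.  User-extendable via the
# ``prototype_map`` argument of :func:`resolve_rmim_class`.
DEFAULT_PROTOTYPE_MAP: dict[str, RmimClass] = {
    "2.16.840.1.113883.10.12.1": RmimClass.CLINICAL_DOCUMENT,
    "2.16.840.1.113883.10.12.2": RmimClass.CLINICAL_DOCUMENT,
    "2.16.840.1.113883.10.12.101": RmimClass.PATIENT_ROLE,
    "2.16.840.1.113883.10.12.102": RmimClass.ASSIGNED_ENTITY,
    "2.16.840.1.113883.10.12.104": RmimClass.ORGANIZATION,
    "2.16.840.1.113883.10.12.113": RmimClass.ENCOUNTER,
    "2.16.840.1.113883.10.12.152": RmimClass.PATIENT,
    "2.16.840.1.113883.10.12.201": RmimClass.SECTION,
    "2.16.840.1.113883.10.12.301": RmimClass.OBSERVATION,
    "2.16.840.1.113883.10.12.302": RmimClass.OBSERVATION_MEDIA,
    "2.16.840.1.113883.10.12.303": RmimClass.ACT,
    "2.16.840.1.113883.10.12.304": RmimClass.ENCOUNTER,
    "2.16.840.1.113883.10.12.305": RmimClass.PROCEDURE,
    "2.16.840.1.113883.10.12.306": RmimClass.REGION_OF_INTEREST,
    "2.16.840.1.113883.10.12.307": RmimClass.SUBSTANCE_ADMINISTRATION,
    "2.16.840.1.113883.10.12.308": RmimClass.SUPPLY,
    "2.16.840.1.113883.10.12.309": RmimClass.ORGANIZER,
    "2.16.840.1.113883.10.12.310": RmimClass.SPECIMEN,
}


def _local(tag) -> str:
    if not isinstance(tag, str):  # comments / PIs
        return ""
    return tag.rsplit("}", 1)[-1]


def _canonical_name(raw: str, node: etree._Element) -> str:
    """Normalize ``prefix:name`` to the canonical hl7/sdtc prefixes."""
    if ":" in raw:
        prefix, local = raw.split(":", 1)
    else:
        prefix, local = "", raw
    uri = node.nsmap.get(prefix or None)
    if uri == HL7_NS or prefix in ("", "hl7") and uri is None:
        return f"hl7:{local}"
    if uri == SDTC_NS or (uri is None and prefix == "sdtc"):
        return f"sdtc:{local}"
    if uri is None:
        # Unknown prefix with no declaration: assume the HL7 namespace,
        # which is what decor files mean in practice.
        return f"hl7:{local}"
    return raw


def _parse_multiplicity(node: etree._Element) -> tuple[int, int]:
    lo = node.get("minimumMultiplicity")
    hi = node.get("maximumMultiplicity")
    min_occurs = int(lo) if lo not in (None, "") else 0
    if hi in (None, ""):
        max_occurs = 1 if min_occurs <= 1 else min_occurs
    elif hi == "*":
        max_occurs = UNBOUNDED
    else:
        max_occurs = int(hi)
    return min_occurs, max_occurs


def _parse_conformance(node: etree._Element, min_occurs: int) -> Conformance:
    if node.get("isMandatory", "").lower() == "true":
        return Conformance.MANDATORY
    conf = node.get("conformance")
    if conf in _CONFORMANCE_MAP:
        return _CONFORMANCE_MAP[conf]
    return Conformance.REQUIRED if min_occurs >= 1 else Conformance.OPTIONAL


def _parse_bindings(node: etree._Element, warnings: list[str]) -> list[VocabularyBinding]:
    bindings = []
    for voc in node:
        if _local(voc.tag) != "vocabulary":
            continue
        strength = _STRENGTH_MAP.get(
            (voc.get("strength") or "").lower(), BindingStrength.UNSPECIFIED
        )
        value_set = voc.get("valueSet")
        code = voc.get("code")
        system = voc.get("codeSystem")
        if value_set:
            bindings.append(
                VocabularyBinding(
                    kind=BindingKind.VALUE_SET,
                    value_set_id=value_set,
                    code_system_oid=system,
                    code_system_name=voc.get("codeSystemName"),
                    strength=strength,
                )
            )
        elif code and system:
            bindings.append(
                VocabularyBinding(
                    kind=BindingKind.FIXED_CODE,
                    code=code,
                    code_system_oid=system,
                    code_system_name=voc.get("codeSystemName"),
                    strength=strength,
                )
            )
        else:
            warnings.append(
                f"incomplete <vocabulary> on {node.get('name')!r}: skipped"
            )
    return bindings


def _desc_text(node: etree._Element) -> str:
    for child in node:
        if _local(child.tag) == "desc":
            return "".join(child.itertext()).strip()
    return ""


def _make_template_id(
    oid: str, effective_date: Optional[str] = None, display_name: Optional[str] = None
) -> TemplateId:
    return TemplateId(
        oid=oid, effective_date=effective_date or None, display_name=display_name
    )


class _TemplateReader:
    """Stateful walk over one ``<template>`` element."""

    def __init__(self, node: etree._Element, warnings: list[str]):
        self.node = node
        self.warnings = warnings
        self.elements: list[TemplateElement] = []
        self.references: list[TemplateReference] = []

    def read(self) -> TemplateDefinition:
        node = self.node
        oid = node.get("id", "")
        tid = _make_template_id(
            oid,
            node.get("effectiveDate"),
            node.get("displayName") or node.get("name"),
        )
        status = _STATUS_MAP.get((node.get("statusCode") or "").lower(), Status.OTHER)
        level = TemplateLevel.UNSPECIFIED
        context_element = ""
        for child in node:
            tag = _local(child.tag)
            if tag == "classification":
                level = _LEVEL_BY_CLASSIFICATION.get(
                    (child.get("type") or "").lower(), level
                )
            elif tag == "relationship":
                if (child.get("type") or "").upper() == "SPEC" and child.get("template"):
                    self.references.append(
                        TemplateReference(
                            kind=ReferenceKind.SPECIALIZES,
                            target=_make_template_id(
                                child.get("template"), child.get("flexibility")
                            ),
                        )
                    )
            elif tag == "context":
                context_element = child.get("element") or ""
                if context_element:
                    context_element = _canonical_name(context_element, child)

        top_elements = [c for c in node if _local(c.tag) == "element"]
        root_element_name = ""
        body_roots: list[etree._Element] = top_elements
        unwrap = False
        if len(top_elements) == 1:
            name = _canonical_name(top_elements[0].get("name", ""), top_elements[0])
            if context_element and context_element == name:
                unwrap = True
            elif not context_element and level in (
                TemplateLevel.DOCUMENT,
                TemplateLevel.SECTION,
                TemplateLevel.ENTRY,
            ):
                unwrap = True
            if unwrap:
                root_element_name = name
        if not root_element_name and context_element:
            root_element_name = context_element
        if not root_element_name and level is TemplateLevel.DOCUMENT:
            root_element_name = "hl7:ClinicalDocument"

        if unwrap:
            root = top_elements[0]
            if root.get("contains"):
                self.warnings.append(
                    f"template {oid}: root element cannot be a contains slot; ignored"
                )
            self._walk_children(root, prefix="")
            for extra in node:
                if _local(extra.tag) == "include":
                    self._read_include(extra, via_path="")
                elif _local(extra.tag) == "choice":
                    self._walk_choice(extra, prefix="", group=1)
        else:
            group = 0
            for child in node:
                tag = _local(child.tag)
                if tag == "element":
                    self._read_element(child, prefix="")
                elif tag == "include":
                    self._read_include(child, via_path="")
                elif tag == "choice":
                    group += 1
                    self._walk_choice(child, prefix="", group=group)
                elif tag in (
                    "classification",
                    "relationship",
                    "context",
                    "desc",
                    "attribute",
                    "",
                ):
                    continue
                else:
                    self.warnings.append(
                        f"template {oid}: skipped unknown child <{tag}>"
                    )

        return TemplateDefinition(
            id=tid,
            status=status,
            level=level,
            description=_desc_text(node),
            root_element_name=root_element_name,
            elements=self.elements,
            references=self.references,
        )

    # -- element tree ------------------------------------------------------

    def _walk_children(self, node: etree._Element, prefix: str, forced_optional=False):
        group = 0
        for child in node:
            tag = _local(child.tag)
            if tag == "element":
                self._read_element(child, prefix, forced_optional)
            elif tag == "include":
                self._read_include(child, via_path=prefix.rstrip("/"))
            elif tag == "choice":
                group += 1
                self._walk_choice(child, prefix, group)

    def _walk_choice(self, node: etree._Element, prefix: str, group: int):
        # Choice branches are flattened: every branch becomes optional
        # (min lowered to 0) and tagged so the alternation is still visible.
        for child in node:
            tag = _local(child.tag)
            if tag == "element":
                self._read_element(child, prefix, forced_optional=True, choice=group)
            elif tag == "include":
                self._read_include(child, via_path=prefix.rstrip("/"), forced_optional=True)

    def _read_element(
        self,
        node: etree._Element,
        prefix: str,
        forced_optional: bool = False,
        choice: int = 0,
    ) -> None:
        raw_name = node.get("name", "")
        if not raw_name:
            self.warnings.append("element without @name skipped")
            return
        name = _canonical_name(raw_name, node)
        path = f"{prefix}{name}"
        min_occurs, max_occurs = _parse_multiplicity(node)
        if forced_optional:
            min_occurs = 0
        conformance = _parse_conformance(node, min_occurs)
        desc = _desc_text(node)
        if choice:
            desc = f"{desc} [choice group {choice}]".strip()
        fixed_attrs = [
            (a.get("name", ""), a.get("value", ""))
            for a in node
            if _local(a.tag) == "attribute" and a.get("name")
        ]
        contains = node.get("contains")
        contains_ref = None
        if contains:
            contains_ref = _make_template_id(contains, node.get("flexibility"))
            self.references.append(
                TemplateReference(
                    kind=ReferenceKind.CONTAINS,
                    target=contains_ref,
                    via_path=path,
                    min_occurs=min_occurs,
                    max_occurs=max_occurs,
                )
            )
        element = TemplateElement(
            relative_path=path,
            description=desc,
            datatype=node.get("datatype", "") or "",
            min_occurs=min_occurs,
            max_occurs=max_occurs,
            conformance=conformance,
            bindings=_parse_bindings(node, self.warnings),
            contains_ref=contains_ref,
            fixed_attributes=fixed_attrs,
        )
        self.elements.append(element)
        if contains_ref is None:
            self._walk_children(node, prefix=f"{path}/")
        elif any(_local(c.tag) == "element" for c in node):
            self.warnings.append(
                f"contains slot {path} has child elements: children ignored"
            )

    def _read_include(
        self, node: etree._Element, via_path: str, forced_optional: bool = False
    ) -> None:
        ref = node.get("ref")
        if not ref:
            self.warnings.append("include without @ref skipped")
            return
        min_occurs, max_occurs = _parse_multiplicity(node)
        if forced_optional:
            min_occurs = 0
        self.references.append(
            TemplateReference(
                kind=ReferenceKind.INCLUDE,
                target=_make_template_id(ref, node.get("flexibility")),
                via_path=via_path,
                min_occurs=min_occurs,
                max_occurs=max_occurs,
            )
        )


def parse_repository(source: Source, strict: bool = False) -> TemplateRepository:
    """Read a decor-dialect template repository file into the domain model.

    Parameters
    ----------
    source:
        Path, bytes, or binary stream holding the decor XML.
    strict:
        If true, duplicate (oid, effective_date) pairs raise instead of
        last-wins with a warning.
    """
    if isinstance(source, bytes):
        stream: Union[IO[bytes], str, os.PathLike] = io.BytesIO(source)
        uri = "<bytes>"
    else:
        stream = source
        uri = str(source) if isinstance(source, (str, os.PathLike)) else "<stream>"
    try:
        tree = etree.parse(stream)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise RepositoryParseError(f"cannot parse {uri}: {exc}") from exc

    root = tree.getroot()
    rules = root if _local(root.tag) == "rules" else None
    if rules is None:
        for node in root.iter():
            if _local(node.tag) == "rules":
                rules = node
                break
    if rules is None:
        raise NotATemplateRepositoryError(
            f"{uri}: not a template repository (no <rules> element)"
        )

    repo = TemplateRepository(source_uri=uri)
    n_templates = 0
    for child in rules:
        tag = _local(child.tag)
        if tag == "template":
            reader = _TemplateReader(child, repo.warnings)
            template = reader.read()
            if not template.id.oid:
                repo.warnings.append("template without @id skipped")
                continue
            repo.add(template, strict=strict)
            n_templates += 1
        elif tag:
            repo.warnings.append(f"skipped unknown <rules> child <{tag}>")
    if n_templates == 0:
        repo.warnings.append("repository contains no templates")
    return repo


def resolve_rmim_class(
    template: TemplateDefinition,
    repository: TemplateRepository,
    prototype_map: Optional[dict[str, RmimClass]] = None,
    max_depth: int = 10,
) -> RmimClass:
    """Determine the CDA R-MIM class a template constrains.

    Resolution order (first match wins, deterministic):

    1. a ``specializes`` target whose OID is in ``prototype_map``;
    2. a transitive ``specializes`` chase within the repository (bounded);
    3. the template's root element name via a fixed name→class table;
    4. :attr:`RmimClass.UNKNOWN`.
    """
    pmap = DEFAULT_PROTOTYPE_MAP if prototype_map is None else prototype_map

    for ref in template.specializes():
        if ref.target.oid in pmap:
            return pmap[ref.target.oid]

    seen = {template.id.key}
    frontier = template.specializes()
    for _ in range(max_depth):
        next_frontier = []
        for ref in frontier:
            parent = repository.get(ref.target)
            if parent is None or parent.id.key in seen:
                continue
            seen.add(parent.id.key)
            for up in parent.specializes():
                if up.target.oid in pmap:
                    return pmap[up.target.oid]
                next_frontier.append(up)
        if not next_frontier:
            break
        frontier = next_frontier

    if template.root_element_name in ELEMENT_NAME_CLASS_TABLE:
        return ELEMENT_NAME_CLASS_TABLE[template.root_element_name]
    return RmimClass.UNKNOWN


def resolve_all_rmim_classes(
    repository: TemplateRepository,
    prototype_map: Optional[dict[str, RmimClass]] = None,
) -> None:
    """Annotate every template in the repository with its resolved class."""
    for template in repository:
        template.rmim_class = resolve_rmim_class(template, repository, prototype_map)
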