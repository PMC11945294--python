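"""Synthetic template repositories and conformant CDA instances.

Every downstream stage (parsing, graph, locators, mapping, export) is
testable without downloading a national template repository: this module
generates decor-dialect repository files with a known ground truth
(document -> section -> entry nesting over include/contains references,
cardinalities, HL7 V3 datatypes, value-set bindings, optionally an
injected dependency cycle) together with CDA instances that realize those
templates, and verifies computed XPath locators against such instances.

The generated XML and its manifest come from the same random draw, so the
manifest *is* the ground truth for counts and expected locators.  All
generation is seeded and byte-deterministic.

Instances carry a ``templateId`` marker on every instantiated template
occurrence, as nationally deployed CDA documents do; locator verification
keys on those markers.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from lxml import etree

from .model import (
    HL7_NS,
    NSMAP,
    SDTC_NS,
    CdaRabbitError,
    ReferenceKind,
    TemplateDefinition,
    TemplateId,
    TemplateLevel,
    TemplateRepository,
)

Key = tuple[str, Optional[str]]

_OID_BASE = "1.2.40.0.34.777"

#: (R-MIM class name, constrained root element) pool for entry templates.
ENTRY_CLASS_POOL = [
    ("Observation", "hl7:observation", "2.16.840.1.113883.10.12.301"),
    ("SubstanceAdministration", "hl7:substanceAdministration", "2.16.840.1.113883.10.12.307"),
    ("Supply", "hl7:supply", "2.16.840.1.113883.10.12.308"),
    ("Act", "hl7:act", "2.16.840.1.113883.10.12.303"),
    ("Procedure", "hl7:procedure", "2.16.840.1.113883.10.12.305"),
    ("Specimen", "hl7:specimenRole", "2.16.840.1.113883.10.12.310"),
]

# Element "plans": each plan is a list of (relative path, datatype,
# min, max, bindable) rows that are emitted together.
_ELEMENT_PLANS = [
    [("hl7:code", "CE", 1, "1", True)],
    [("hl7:text", "ED", 0, "1", False)],
    [("hl7:statusCode", "CS", 1, "1", True)],
    [("hl7:effectiveTime", "IVL_TS", 0, "1", False),
     ("hl7:effectiveTime/hl7:low", "TS", 0, "1", False)],
    [("hl7:value", "PQ", 0, "1", False)],
    [("hl7:id", "II", 1, "*", False)],
]

_DOC_SECTION_VIA = "hl7:component/hl7:structuredBody/hl7:component/hl7:section"

DEFAULT_VOCAB_POOL = [
    "1.2.40.0.34.777.10.1",
    "1.2.40.0.34.777.10.2",
    "2.16.840.1.113883.6.1",
    "2.16.840.1.113883.6.73",
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic repository draw."""

    n_document: int = 2
    n_section: int = 4
    n_entry: int = 6
    contain_density: float = 0.3
    reuse_probability: float = 0.3
    vocab_pool: list[str] = field(default_factory=lambda: list(DEFAULT_VOCAB_POOL))
    inject_cycle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_document, self.n_section, self.n_entry) < 1:
            raise ValueError("counts must be positive")
        for p in (self.contain_density, self.reuse_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class FixtureManifest:
    """Ground truth of one generated fixture."""

    template_count: int = 0
    root_oids: list[str] = field(default_factory=list)
    header_oid: str = ""
    elements_per_template: dict[str, int] = field(default_factory=dict)
    references: list[tuple[str, str, str, str]] = field(default_factory=list)
    expected_locators: dict[str, list[str]] = field(default_factory=dict)
    vocabulary_inventory: dict[str, int] = field(default_factory=dict)

    @property
    def element_count(self) -> int:
        return sum(self.elements_per_template.values())

    @property
    def reference_count(self) -> int:
        return len(self.references)


class LocatorOutcome(str, enum.Enum):
    MATCHED = "matched"
    NOT_INSTANTIATED = "not_instantiated"
    MISMATCH = "mismatch"


@dataclass
class LocatorVerificationReport:
    results: list[tuple[str, str, LocatorOutcome]] = field(default_factory=list)
    # (template oid, absolute path, outcome)

    def count(self, outcome: LocatorOutcome) -> int:
        return sum(1 for r in self.results if r[2] is outcome)

    @property
    def matched(self) -> int:
        return self.count(LocatorOutcome.MATCHED)

    @property
    def not_instantiated(self) -> int:
        return self.count(LocatorOutcome.NOT_INSTANTIATED)

    @property
    def mismatch(self) -> int:
        return self.count(LocatorOutcome.MISMATCH)

    @property
    def total(self) -> int:
        return len(self.results)

    def offending_paths(self) -> list[str]:
        return [p for _, p, o in self.results if o is LocatorOutcome.MISMATCH]


# -- repository generation -------------------------------------------------


@dataclass
class _TemplatePlan:
    oid: str
    name: str
    level: str  # classification type suffix
    rmim_root: str
    spec_prototype: str = ""
    elements: list[tuple] = field(default_factory=list)
    # (path, datatype, min, max, binding or None); binding = (kind, oid, name)
    includes: list[tuple[str, int]] = field(default_factory=list)  # (target, min)
    contains: list[tuple[str, str, str, int]] = field(default_factory=list)
    # (via_path, slot tail, target oid, min)


def _draw_elements(rng: random.Random, spec: FixtureSpec) -> list[tuple]:
    n_plans = rng.randint(1, 3)
    plans = rng.sample(_ELEMENT_PLANS, n_plans)
    rows = []
    for plan in sorted(plans, key=_ELEMENT_PLANS.index):
        for path, datatype, lo, hi, bindable in plan:
            binding = None
            if bindable and rng.random() < 0.6:
                voc = rng.choice(spec.vocab_pool)
                if rng.random() < 0.5:
                    binding = ("valueSet", voc, f"VS-{voc.rsplit('.', 1)[-1]}")
                else:
                    binding = ("code", voc, f"CS-{voc.rsplit('.', 1)[-1]}")
            rows.append((path, datatype, lo, hi, binding))
    return rows


def _plan_fixture(spec: FixtureSpec) -> list[_TemplatePlan]:
    rng = random.Random(spec.seed)
    docs = [
        _TemplatePlan(
            oid=f"{_OID_BASE}.1.{i + 1}",
            name=f"Document{i + 1}",
            level="cdadocumentlevel",
            rmim_root="hl7:ClinicalDocument",
            spec_prototype="2.16.840.1.113883.10.12.2",
        )
        for i in range(spec.n_document)
    ]
    sections = [
        _TemplatePlan(
            oid=f"{_OID_BASE}.2.{i + 1}",
            name=f"Section{i + 1}",
            level="cdasectionlevel",
            rmim_root="hl7:section",
        )
        for i in range(spec.n_section)
    ]
    entries = []
    for i in range(spec.n_entry):
        cls, root, proto = rng.choice(ENTRY_CLASS_POOL)
        entries.append(
            _TemplatePlan(
                oid=f"{_OID_BASE}.3.{i + 1}",
                name=f"Entry{i + 1}{cls}",
                level="cdaentrylevel",
                rmim_root=root,
                spec_prototype=proto if rng.random() < 0.5 else "",
            )
        )
    header = _TemplatePlan(
        oid=f"{_OID_BASE}.9.1",
        name="SharedHeader",
        level="cdaheaderlevel",
        rmim_root="",
        spec_prototype="2.16.840.1.113883.10.12.101",
        elements=[
            ("hl7:recordTarget", "", 1, "1", None),
            ("hl7:recordTarget/hl7:patientRole", "", 1, "1", None),
            ("hl7:recordTarget/hl7:patientRole/hl7:id", "II", 1, "*", None),
            ("hl7:recordTarget/hl7:patientRole/hl7:patient", "", 0, "1", None),
            (
                "hl7:recordTarget/hl7:patientRole/hl7:patient/hl7:administrativeGenderCode",
                "CE",
                0,
                "1",
                ("valueSet", f"{_OID_BASE}.10.9", "AdministrativeGender"),
            ),
        ],
    )

    for plan in docs + sections + entries:
        plan.elements = _draw_elements(rng, spec)
    for doc in docs:
        doc.includes.append((header.oid, 1))

    # round-robin assignment keeps every template reachable; extra links
    # exercise template reuse (multiple locators per template)
    for i, sec in enumerate(sections):
        doc = docs[i % spec.n_document]
        doc.contains.append((_DOC_SECTION_VIA, "hl7:section", sec.oid, rng.choice([0, 1])))
    for doc in docs:
        for sec in sections:
            if not any(c[2] == sec.oid for c in doc.contains):
                if rng.random() < spec.reuse_probability:
                    doc.contains.append((_DOC_SECTION_VIA, "hl7:section", sec.oid, 0))
    for j, ent in enumerate(entries):
        sec = sections[j % spec.n_section]
        via = f"hl7:entry/{ent.rmim_root}"
        sec.contains.append((via, ent.rmim_root, ent.oid, rng.choice([0, 1])))
    for sec in sections:
        for ent in entries:
            if not any(c[2] == ent.oid for c in sec.contains):
                if rng.random() < spec.contain_density:
                    sec.contains.append(
                        (f"hl7:entry/{ent.rmim_root}", ent.rmim_root, ent.oid, 0)
                    )

    if spec.inject_cycle:
        a = entries[0]
        b = entries[1 % len(entries)]
        a.contains.append((f"hl7:entryRelationship/{b.rmim_root}", b.rmim_root, b.oid, 0))
        if b is not a:
            b.contains.append(
                (f"hl7:entryRelationship/{a.rmim_root}", a.rmim_root, a.oid, 0)
            )

    return docs + sections + entries + [header]


def _plan_element_count(plan: _TemplatePlan) -> int:
    # every path segment the serializer writes becomes one parsed element
    n = len(plan.elements)
    for via, _tail, _target, _min in plan.contains:
        n += via.count("/") + 1
    return n


def _expected_locators(plans: list[_TemplatePlan]) -> dict[str, list[str]]:
    by_oid = {p.oid: p for p in plans}
    out: dict[str, list[str]] = {}

    def add(oid: str, path: str) -> bool:
        paths = out.setdefault(oid, [])
        if path in paths:
            return False
        paths.append(path)
        return True

    def expand(plan: _TemplatePlan, path: str, chain: frozenset) -> None:
        for target_oid, _min in plan.includes:
            if target_oid in chain:
                continue
            if add(target_oid, path):
                expand(by_oid[target_oid], path, chain | {target_oid})
        for via, _tail, target_oid, _min in plan.contains:
            if target_oid in chain:
                continue
            child = f"{path}/{via}"
            if add(target_oid, child):
                expand(by_oid[target_oid], child, chain | {target_oid})

    for plan in plans:
        if plan.level == "cdadocumentlevel":
            anchor = "/hl7:ClinicalDocument"
            add(plan.oid, anchor)
            expand(plan, anchor, frozenset({plan.oid}))
    return out


def _emit_element_tree(parent: etree._Element, rows: list[tuple]) -> None:
    nodes: dict[str, etree._Element] = {}
    for path, datatype, lo, hi, binding in rows:
        head, _, leaf = path.rpartition("/")
        container = nodes[head] if head else parent
        el = etree.SubElement(container, "element", name=leaf)
        el.set("minimumMultiplicity", str(lo))
        el.set("maximumMultiplicity", hi)
        if datatype:
            el.set("datatype", datatype)
        if lo >= 1:
            el.set("conformance", "R")
        if binding is not None:
            kind, voc, display = binding
            if kind == "valueSet":
                etree.SubElement(
                    el, "vocabulary", valueSet=voc, codeSystemName=display
                )
            else:
                etree.SubElement(
                    el,
                    "vocabulary",
                    code="C1",
                    codeSystem=voc,
                    codeSystemName=display,
                )
        nodes[path] = el


def _emit_contains_chain(
    parent: etree._Element, via: str, target: str, lo: int
) -> None:
    segments = via.split("/")
    node = parent
    for seg in segments[:-1]:
        node = etree.SubElement(node, "element", name=seg)
        node.set("minimumMultiplicity", "0")
        node.set("maximumMultiplicity", "1")
    slot = etree.SubElement(node, "element", name=segments[-1], contains=target)
    slot.set("minimumMultiplicity", str(lo))
    slot.set("maximumMultiplicity", "1")


def generate_fixture_repository(spec: FixtureSpec) -> tuple[bytes, FixtureManifest]:
    """Emit a well-formed decor file and its ground-truth manifest.

    The same seed always yields byte-identical XML.
    """
    plans = _plan_fixture(spec)
    manifest = FixtureManifest(
        template_count=len(plans),
        root_oids=[p.oid for p in plans if p.level == "cdadocumentlevel"],
        header_oid=next(p.oid for p in plans if p.level == "cdaheaderlevel"),
    )
    root = etree.Element("decor", nsmap={"hl7": HL7_NS, "sdtc": SDTC_NS})
    rules = etree.SubElement(root, "rules")
    for plan in plans:
        t = etree.SubElement(rules, "template", id=plan.oid, name=plan.name)
        t.set("displayName", plan.name)
        t.set("statusCode", "active")
        etree.SubElement(t, "classification", type=plan.level)
        desc = etree.SubElement(t, "desc")
        desc.text = f"Synthetic template {plan.name}"
        if plan.spec_prototype:
            etree.SubElement(
                t, "relationship", type="SPEC", template=plan.spec_prototype
            )
        for target, lo in plan.includes:
            inc = etree.SubElement(t, "include", ref=target)
            inc.set("minimumMultiplicity", str(lo))
            inc.set("maximumMultiplicity", "1")
        if plan.rmim_root:
            wrapper = etree.SubElement(t, "element", name=plan.rmim_root)
            wrapper.set("minimumMultiplicity", "1")
            wrapper.set("maximumMultiplicity", "1")
            body = wrapper
        else:
            body = t
        _emit_element_tree(body, plan.elements)
        for via, _tail, target, lo in plan.contains:
            _emit_contains_chain(body, via, target, lo)

        manifest.elements_per_template[plan.oid] = _plan_element_count(plan)
        for target, _lo in plan.includes:
            manifest.references.append((plan.oid, "include", target, ""))
        for via, _tail, target, _lo in plan.contains:
            manifest.references.append((plan.oid, "contains", target, via))
        for _path, _dt, _lo, _hi, binding in plan.elements:
            if binding is not None:
                key = binding[1]
                manifest.vocabulary_inventory[key] = (
                    manifest.vocabulary_inventory.get(key, 0) + 1
                )

    manifest.expected_locators = _expected_locators(plans)
    blob = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    return blob, manifest


# -- instance generation ---------------------------------------------------


def _qname(prefixed: str) -> etree.QName:
    prefix, _, local = prefixed.partition(":")
    uri = {"hl7": HL7_NS, "sdtc": SDTC_NS}.get(prefix, HL7_NS)
    return etree.QName(uri, local)


def _fill_content(el: etree._Element, element, rng: random.Random) -> None:
    datatype = element.datatype
    binding = element.bindings[0] if element.bindings else None
    for attr, value in element.fixed_attributes:
        if ":" not in attr:
            el.set(attr, value)
    if datatype in ("TS", "IVL_TS"):
        el.set("value", "20200101")
    elif datatype in ("CE", "CD", "CV", "CS"):
        if binding is not None and binding.code:
            el.set("code", binding.code)
            if datatype != "CS" and binding.code_system_oid:
                el.set("codeSystem", binding.code_system_oid)
        else:
            el.set("code", f"X{rng.randint(1, 9)}")
            if datatype != "CS":
                el.set("codeSystem", "2.999.9.9")
    elif datatype == "PQ":
        el.set("value", str(rng.randint(1, 99)))
        el.set("unit", "1")
    elif datatype == "II":
        el.set("root", "2.999.1")
        el.set("extension", str(rng.randint(1000, 9999)))
    elif datatype in ("ST", "ED", "PN", "ON", "AD"):
        el.text = "text"


def generate_conformant_instance(
    repository: TemplateRepository,
    root: TemplateId,
    fill_policy: str = "minimal",
    seed: int = 0,
) -> bytes:
    """Emit a CDA instance realizing a document-level template.

    ``minimal`` fills only paths with min_occurs >= 1; ``all_optional``
    additionally fills every optional element and reference slot once.
    Every instantiated template occurrence carries a ``templateId`` child
    with its OID.  Cycle edges are instantiated at most once (one unroll).
    """
    if fill_policy not in ("minimal", "all_optional"):
        raise CdaRabbitError(f"unknown fill policy {fill_policy!r}")
    root_def = repository.get(root)
    if root_def is None or root_def.level is not TemplateLevel.DOCUMENT:
        raise CdaRabbitError(f"instance root {root.oid} is not a document-level template")
    rng = random.Random(seed)
    everything = fill_policy == "all_optional"

    root_name = root_def.root_element_name or "hl7:ClinicalDocument"
    doc = etree.Element(_qname(root_name), nsmap={"hl7": HL7_NS, "sdtc": SDTC_NS})

    def ensure_path(base: etree._Element, relpath: str, cache: dict) -> etree._Element:
        node = base
        walked = ""
        for seg in relpath.split("/"):
            walked = f"{walked}/{seg}" if walked else seg
            hit = cache.get(walked)
            if hit is None:
                hit = etree.SubElement(node, _qname(seg))
                cache[walked] = hit
            node = hit
        return node

    def apply(node: etree._Element, tdef: TemplateDefinition, chain: tuple, expand: bool):
        etree.SubElement(node, _qname("hl7:templateId"), root=tdef.id.oid)
        cache: dict[str, etree._Element] = {}
        for element in tdef.elements:
            if element.contains_ref is not None:
                continue
            if not everything and element.min_occurs < 1:
                continue
            leaf = ensure_path(node, element.relative_path, cache)
            _fill_content(leaf, element, rng)
        if not expand:
            return
        for ref in tdef.containment_references():
            if not everything and ref.min_occurs < 1:
                continue
            target = repository.get(ref.target)
            if target is None:
                continue
            sub_expand = target.id.key not in chain
            if ref.via_path:
                slot = node
                for seg in ref.via_path.split("/"):
                    slot = etree.SubElement(slot, _qname(seg))
                apply(slot, target, chain + (target.id.key,), sub_expand)
            else:
                apply(node, target, chain + (target.id.key,), sub_expand)

    apply(doc, root_def, (root_def.id.key,), True)
    return etree.tostring(doc, xml_declaration=True, encoding="UTF-8", pretty_print=True)


# -- locator verification --------------------------------------------------


def _chain_is_optional(locator, repository: Optional[TemplateRepository]) -> bool:
    if repository is None:
        return True
    prov = locator.provenance
    for i in range(1, len(prov)):
        parent_id, _ = prov[i - 1]
        hop_id, via = prov[i]
        parent = repository.get(parent_id)
        if parent is None:
            return True
        for ref in parent.containment_references():
            if ref.target.oid == hop_id.oid and ref.via_path == via:
                if ref.min_occurs == 0:
                    return True
                break
    return False


def verify_locators(
    instance: bytes,
    locators: dict[Key, list],
    repository: Optional[TemplateRepository] = None,
) -> LocatorVerificationReport:
    """Evaluate every locator against a CDA instance.

    A locator is *matched* when at least one selected node carries the
    template's OID in a ``templateId`` child.  When no selected node
    carries it, the outcome is *not_instantiated* if the containment chain
    is optional somewhere (checked against ``repository`` when given) and
    *mismatch* otherwise.
    """
    try:
        root = etree.fromstring(instance)
    except etree.XMLSyntaxError as exc:
        raise CdaRabbitError(f"malformed instance: {exc}") from exc
    tree = etree.ElementTree(root)
    root_tids = {
        t.get("root")
        for t in root.findall(f"{{{HL7_NS}}}templateId")
    }

    report = LocatorVerificationReport()
    for key, locs in locators.items():
        oid = key[0]
        for loc in locs:
            try:
                nodes = tree.xpath(loc.absolute_path, namespaces=NSMAP)
            except etree.XPathError as exc:
                raise CdaRabbitError(
                    f"invalid locator XPath {loc.absolute_path!r}: {exc}"
                ) from exc
            carried = False
            for node in nodes:
                for tid in node.findall(f"{{{HL7_NS}}}templateId"):
                    if tid.get("root") == oid:
                        carried = True
                        break
                if carried:
                    break
            if carried:
                outcome = LocatorOutcome.MATCHED
            else:
                foreign_root = (
                    loc.provenance and loc.provenance[0][0].oid not in root_tids
                )
                if foreign_root or _chain_is_optional(loc, repository):
                    outcome = LocatorOutcome.NOT_INSTANTIATED
                else:
                    outcome = LocatorOutcome.MISMATCH
            report.results.append((oid, loc.absolute_path, outcome))
    return report


# -- bundled demonstration repository --------------------------------------


def demo_repository_bytes() -> bytes:
    """The frozen synthetic demonstration repository bundled with the
    package: two document-level templates (a discharge summary and a
    laboratory report) expanding to 13 reachable templates with ATC- and
    LOINC-bound entries."""
    return (
        resources.files("cdarabbit.data").joinpath("mini_repository.xml").read_bytes()
    )


def demo_repository_path() -> str:
    return str(resources.files("cdarabbit.data").joinpath("mini_repository.xml"))
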