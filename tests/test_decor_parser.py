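"""Parsing of decor-dialect template repositories into the domain model."""

import pytest
from lxml import etree

from cdarabbit import (
    NSMAP,
    RmimClass,
    TemplateId,
    TemplateLevel,
    parse_repository,
    resolve_rmim_class,
)
from cdarabbit.decor_parser import (
    DEFAULT_PROTOTYPE_MAP,
    NotATemplateRepositoryError,
    RepositoryParseError,
)
from cdarabbit.model import (
    UNBOUNDED,
    BindingKind,
    CdaRabbitError,
    Conformance,
    ReferenceKind,
    TemplateRepository,
)

from conftest import make_decor


def test_template_ids_preserved_in_document_order():
    body = "".join(
        f'<template id="1.2.3.{i}" name="T{i}" statusCode="active"/>' for i in range(5)
    )
    repo = parse_repository(make_decor(body))
    assert len(repo) == 5
    assert [t.id.oid for t in repo] == [f"1.2.3.{i}" for i in range(5)]


def test_element_with_datatype_and_value_set_binding():
    body = """
    <template id="1.2.3" name="Obs" statusCode="active">
      <classification type="cdaentrylevel"/>
      <element name="hl7:observation" minimumMultiplicity="1" maximumMultiplicity="1">
        <element name="hl7:code" datatype="CE" minimumMultiplicity="1" maximumMultiplicity="1">
          <vocabulary valueSet="1.2.9.9" codeSystemName="LOINC"/>
        </element>
      </element>
    </template>
    """
    repo = parse_repository(make_decor(body))
    (template,) = list(repo)
    assert template.root_element_name == "hl7:observation"
    (code,) = template.elements
    assert code.relative_path == "hl7:code"
    assert code.datatype == "CE"
    (binding,) = code.bindings
    assert binding.kind is BindingKind.VALUE_SET
    assert binding.value_set_id == "1.2.9.9"
    assert binding.code_system_name == "LOINC"


def test_empty_rules_element_yields_no_templates_and_a_warning():
    repo = parse_repository(make_decor(""))
    assert len(repo) == 0
    assert any("no templates" in w for w in repo.warnings)


def test_unknown_rules_child_is_skipped_with_warning():
    repo = parse_repository(make_decor('<template id="1.2.3"/><banana/>'))
    assert len(repo) == 1
    assert any("banana" in w for w in repo.warnings)


def test_malformed_xml_raises_parse_error_with_location():
    with pytest.raises(RepositoryParseError) as err:
        parse_repository(b"<decor><rules><template")
    assert "line" in str(err.value).lower()


def test_missing_rules_element_is_not_a_repository():
    with pytest.raises(NotATemplateRepositoryError):
        parse_repository(b"<someOtherDocument/>")


def test_duplicate_template_last_wins_unless_strict():
    body = (
        '<template id="1.2.3" name="A" statusCode="draft"/>'
        '<template id="1.2.3" name="B" statusCode="active"/>'
    )
    repo = parse_repository(make_decor(body))
    assert len(repo) == 1
    assert next(iter(repo)).display_name == "B"
    assert any("duplicate" in w for w in repo.warnings)
    with pytest.raises(CdaRabbitError):
        parse_repository(make_decor(body), strict=True)


def test_nested_elements_flatten_to_slash_paths_in_document_order():
    body = """
    <template id="1.2.3" name="T" statusCode="active">
      <classification type="cdaentrylevel"/>
      <element name="hl7:observation" minimumMultiplicity="1" maximumMultiplicity="1">
        <element name="hl7:effectiveTime" datatype="IVL_TS" minimumMultiplicity="0" maximumMultiplicity="1">
          <element name="hl7:low" datatype="TS" minimumMultiplicity="0" maximumMultiplicity="1"/>
        </element>
        <element name="hl7:value" datatype="PQ" minimumMultiplicity="0" maximumMultiplicity="*"/>
      </element>
    </template>
    """
    repo = parse_repository(make_decor(body))
    (template,) = list(repo)
    paths = [e.relative_path for e in template.elements]
    assert paths == ["hl7:effectiveTime", "hl7:effectiveTime/hl7:low", "hl7:value"]
    assert template.elements[2].max_occurs == UNBOUNDED


def test_contains_attribute_becomes_reference_and_slot_element():
    body = """
    <template id="1.2.3" name="Sec" statusCode="active">
      <classification type="cdasectionlevel"/>
      <element name="hl7:section" minimumMultiplicity="1" maximumMultiplicity="1">
        <element name="hl7:entry" minimumMultiplicity="0" maximumMultiplicity="1">
          <element name="hl7:observation" contains="9.9.9" minimumMultiplicity="0" maximumMultiplicity="1"/>
        </element>
      </element>
    </template>
    """
    repo = parse_repository(make_decor(body))
    (template,) = list(repo)
    (ref,) = template.containment_references()
    assert ref.kind is ReferenceKind.CONTAINS
    assert ref.target.oid == "9.9.9"
    assert ref.via_path == "hl7:entry/hl7:observation"
    slot = template.elements[-1]
    assert slot.contains_ref is not None and slot.contains_ref.oid == "9.9.9"


def test_root_level_include_has_empty_via_path():
    body = """
    <template id="1.2.3" name="Doc" statusCode="active">
      <classification type="cdadocumentlevel"/>
      <include ref="4.5.6" minimumMultiplicity="1" maximumMultiplicity="1"/>
    </template>
    <template id="4.5.6" name="Header" statusCode="active">
      <classification type="cdaheaderlevel"/>
      <element name="hl7:recordTarget" minimumMultiplicity="1" maximumMultiplicity="1"/>
    </template>
    """
    repo = parse_repository(make_decor(body))
    doc = repo.get(TemplateId("1.2.3"))
    (ref,) = doc.containment_references()
    assert ref.kind is ReferenceKind.INCLUDE
    assert ref.via_path == ""
    # document-level invariant: constrained root is the CDA document element
    assert doc.root_element_name == "hl7:ClinicalDocument"
    # header without a context declaration is not unwrapped
    header = repo.get(TemplateId("4.5.6"))
    assert header.root_element_name == ""
    assert header.elements[0].relative_path == "hl7:recordTarget"


def test_choice_branches_flattened_optional_and_tagged():
    body = """
    <template id="1.2.3" name="T" statusCode="active">
      <classification type="cdaentrylevel"/>
      <element name="hl7:observation" minimumMultiplicity="1" maximumMultiplicity="1">
        <choice>
          <element name="hl7:value" datatype="PQ" minimumMultiplicity="1" maximumMultiplicity="1"/>
          <element name="hl7:text" datatype="ED" minimumMultiplicity="1" maximumMultiplicity="1"/>
        </choice>
      </element>
    </template>
    """
    repo = parse_repository(make_decor(body))
    (template,) = list(repo)
    assert [e.relative_path for e in template.elements] == ["hl7:value", "hl7:text"]
    assert all(e.min_occurs == 0 for e in template.elements)
    assert all("choice group 1" in e.description for e in template.elements)


def test_fixed_attributes_and_mandatory_conformance():
    body = """
    <template id="1.2.3" name="T" statusCode="active">
      <classification type="cdaentrylevel"/>
      <element name="hl7:observation" minimumMultiplicity="1" maximumMultiplicity="1">
        <element name="hl7:statusCode" datatype="CS" isMandatory="true"
                 minimumMultiplicity="1" maximumMultiplicity="1">
          <attribute name="code" value="completed"/>
        </element>
      </element>
    </template>
    """
    repo = parse_repository(make_decor(body))
    (el,) = next(iter(repo)).elements
    assert el.conformance is Conformance.MANDATORY
    assert el.fixed_attributes == [("code", "completed")]


def test_foreign_hl7_prefix_is_canonicalized():
    xml = b"""<?xml version="1.0"?>
    <decor xmlns:cda="urn:hl7-org:v3">
      <rules>
        <template id="1.2.3" name="T" statusCode="active">
          <classification type="cdaentrylevel"/>
          <element name="cda:observation" minimumMultiplicity="1" maximumMultiplicity="1">
            <element name="cda:code" datatype="CE" minimumMultiplicity="1" maximumMultiplicity="1"/>
          </element>
        </template>
      </rules>
    </decor>"""
    repo = parse_repository(xml)
    (template,) = list(repo)
    assert template.root_element_name == "hl7:observation"
    assert template.elements[0].relative_path == "hl7:code"


def test_reparsing_yields_identical_repository(demo_repo):
    from cdarabbit import demo_repository_path

    again = parse_repository(demo_repository_path())
    assert [t.id for t in again] == [t.id for t in demo_repo]
    assert [
        [e.relative_path for e in t.elements] for t in again
    ] == [[e.relative_path for e in t.elements] for t in demo_repo]


def test_every_relative_path_is_valid_xpath(demo_repo):
    for template in demo_repo:
        for element in template.elements:
            etree.XPath(element.relative_path, namespaces=NSMAP)  # must not raise


class TestRmimResolution:
    def test_prototype_lineage_wins(self):
        body = """
        <template id="1.2.3" name="P" statusCode="active">
          <classification type="cdaheaderlevel"/>
          <relationship type="SPEC" template="2.16.840.1.113883.10.12.152"/>
        </template>
        """
        repo = parse_repository(make_decor(body))
        assert (
            resolve_rmim_class(next(iter(repo)), repo) is RmimClass.PATIENT
        )
        assert DEFAULT_PROTOTYPE_MAP["2.16.840.1.113883.10.12.152"] is RmimClass.PATIENT

    def test_transitive_specialization_chase(self):
        body = """
        <template id="1.2.3" name="Child" statusCode="active">
          <relationship type="SPEC" template="1.2.4"/>
        </template>
        <template id="1.2.4" name="Parent" statusCode="active">
          <relationship type="SPEC" template="2.16.840.1.113883.10.12.301"/>
        </template>
        """
        repo = parse_repository(make_decor(body))
        child = repo.get(TemplateId("1.2.3"))
        assert resolve_rmim_class(child, repo) is RmimClass.OBSERVATION

    def test_root_element_fallback(self):
        body = """
        <template id="1.2.3" name="T" statusCode="active">
          <classification type="cdaentrylevel"/>
          <element name="hl7:observation" minimumMultiplicity="1" maximumMultiplicity="1"/>
        </template>
        """
        repo = parse_repository(make_decor(body))
        assert resolve_rmim_class(next(iter(repo)), repo) is RmimClass.OBSERVATION

    def test_unrecognized_template_falls_back_to_unknown(self):
        repo = parse_repository(
            make_decor('<template id="1.2.3" name="T" statusCode="active"/>')
        )
        assert resolve_rmim_class(next(iter(repo)), repo) is RmimClass.UNKNOWN


class TestVersionResolution:
    def _repo_with_versions(self):
        body = """
        <template id="1.2.3" name="Old" effectiveDate="2019-01-01T00:00:00" statusCode="active"/>
        <template id="1.2.3" name="New" effectiveDate="2021-01-01T00:00:00" statusCode="active"/>
        <template id="1.2.3" name="Draft" effectiveDate="2023-01-01T00:00:00" statusCode="draft"/>
        """
        return parse_repository(make_decor(body))

    def test_dateless_reference_prefers_latest_active(self):
        repo = self._repo_with_versions()
        assert repo.get(TemplateId("1.2.3")).display_name == "New"

    def test_preference_override_returns_latest_overall(self):
        repo = self._repo_with_versions()
        hit = repo.get(TemplateId("1.2.3"), prefer_active=False)
        assert hit.display_name == "Draft"

    def test_exact_versioned_reference(self):
        repo = self._repo_with_versions()
        hit = repo.get(TemplateId("1.2.3", "2019-01-01T00:00:00"))
        assert hit.display_name == "Old"


def test_template_id_rejects_non_oid():
    with pytest.raises(ValueError):
        TemplateId("not-an-oid")


def test_level_classification_read(demo_repo):
    levels = {t.id.oid: t.level for t in demo_repo}
    assert levels["1.2.40.0.34.999.1.1"] is TemplateLevel.DOCUMENT
    assert levels["1.2.40.0.34.999.2.1"] is TemplateLevel.HEADER
    assert levels["1.2.40.0.34.999.3.1"] is TemplateLevel.SECTION
    assert levels["1.2.40.0.34.999.4.1"] is TemplateLevel.ENTRY
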