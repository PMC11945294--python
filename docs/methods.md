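# Methods

## Problem

Designing an Extract-Transform-Load (ETL) process from HL7 CDA documents
into the OMOP Common Data Model normally requires profiling patient-level
source data. CDA-based data sources, however, are governed by *CDA
Templates*: OID-identified constraint definitions on the CDA R-MIM (the
generic HL7 V3 clinical-document model) that prescribe, per document type,
which elements occur where, how often, and bound to which terminologies.
`cdarabbit` exploits that: everything a structural ETL design needs can be
derived from the template repository alone, before any patient-level
document is available. The output is shaped for OHDSI's design toolchain —
templates presented as source *tables*, their elements as *fields*,
default mapping suggestions as arcs — so that ETL design proceeds in
Rabbit-In-a-Hat exactly as it would for a relational source.

## Template model and parsing

The parser reads the ART-DECOR "decor" XML dialect: template definitions
as `<template>` children of a `<rules>` element. The subset interpreted:

* **Cardinality** from `minimumMultiplicity`/`maximumMultiplicity`
  (`"*"` → unbounded); **conformance** from `@conformance` (`R`/`O`/`C`/`NP`)
  and `@isMandatory`.
* **Lineage** from `<relationship type="SPEC" template=…>`; this is the
  prototype/specialization link, never a containment edge.
* **Containment** from `element/@contains` (the element becomes a
  reference *slot* carrying no children of its own) and `<include ref=…>`
  (the included template constrains the same context node; empty via-path).
* **Level** from `<classification type="cda…level"/>`. Four levels are
  distinguished — document, header, section, entry — header being the
  natural reading of the standard's four relevant template kinds.
* **Vocabulary bindings** from `<vocabulary>` children: either a value-set
  binding (`@valueSet`) or a fixed code (`@code` + `@codeSystem`).
* **Fixed attribute values** from `<attribute name=… value=…>`, captured
  on the enclosing element (they parameterize locator predicates, not
  mappings).
* `<choice>` groups are flattened: every branch is recorded with
  `min_occurs` lowered to 0 and a choice-group tag in its description.
  This preserves locators without modelling alternation.

Element nesting is flattened into `/`-separated relative paths. All paths
are normalized to a canonical `hl7:` prefix for `urn:hl7-org:v3`
regardless of the prefixes in the source file (extension namespaces such
as `sdtc` keep their conventional prefix), so locator strings are stable
and comparable across files. When a template has exactly one top-level
element (or a `<context element=…>` declaration naming it), that element
is treated as the template's root context and element paths are stored
relative to it.

When several versions of one OID exist, a date-less reference resolves to
the active version with the latest effective date, falling back to the
latest overall; an exact `(oid, effectiveDate)` reference always wins.
This mirrors repository release practice and is overridable
(`prefer_active=False`).

## R-MIM class resolution

The CDA R-MIM class a template constrains drives the default mapping.
Resolution is deterministic, first match wins:

1. a `SPEC` target OID found in the bundled prototype map
   (`2.16.840.1.113883.10.12.*` family → class);
2. a bounded transitive chase of `SPEC` links within the repository;
3. the constrained root element name via a fixed table
   (`hl7:observation` → Observation, `hl7:patient` → Patient, …);
4. `Unknown` (never an exception).

The bundled prototype map is a **reconstruction**: it covers the CDA
structural prototype template family with plausible OID assignments and is
user-extendable via the `prototype_map` argument. Deployments working
against a specific national repository should extend or override it.

## Graph, traversal, cycles, locators

Include/contains references form a directed graph over templates
(`specializes` links never appear as edges; unresolved targets are kept in
a `dangling` list, never dropped silently). Scanning starts from the
document-level templates (user-selectable subset) and walks depth-first in
preorder; every template is reported once, at first encounter.

Cyclic template dependencies are legal under the templating standard. The
policy here is *cut and warn*: cycles are detected (all simple cycles,
reported deduplicated up to rotation, computed via `networkx`), the edge
that would close a cycle is never expanded during traversal or locator
computation, and the cycle report is embedded in the export metadata.

Locators are absolute XPaths from the document root at which a template
occurrence can appear. A document root is anchored at
`/hl7:ClinicalDocument`; a template reached over a contains edge extends
each parent locator with the edge's via-path; include edges inherit the
parent locator unchanged. One locator is kept per distinct containment
chain, deduplicated on the absolute path. Template reuse can make the
locator set combinatorial, so two caps guarantee termination and bounded
output: provenance depth (default 12) and locators per template (default
64); truncation warns.

Locators are plain child paths by default — maximally portable, but a
generic path (e.g. `…/hl7:component/hl7:section`) selects every sibling
occurrence. The `predicates` option appends
`[hl7:templateId/@root='…']` at each hop, making locators selective at
the cost of portability.

## Default mapping suggestions

Table-level suggestions are a pure function of the template's R-MIM class
and the rule table; field-level suggestions match element paths against
glob patterns of the fired rule (first matching pattern wins per element)
and are only ever emitted under an existing table-level suggestion.
Ambiguity is kept, not resolved: all candidate tables are emitted with
ranks, the export draws only rank-1 suggestions as arcs and carries the
alternatives in comments.

The bundled rule table is a **reconstruction** of R-MIM class semantics,
shipped as an editable CSV
(`rmim_class,target_table,rank,element_pattern,target_field`):
Patient/PatientRole → `person`; Encounter → `visit_occurrence`;
Observation → `measurement` | `observation`; SubstanceAdministration and
Supply → `drug_exposure`; Act → `condition_occurrence` | `observation`;
Procedure → `procedure_occurrence`; Specimen → `specimen`;
AssignedEntity/Person → `provider`; Organization → `care_site` (address
elements → `location`); ClinicalDocument → `observation_period` |
`visit_occurrence`. Every rule target is validated against the CDM
catalogue at load time, so an invalid rule fails configuration, not a
scan.

An optional refinement (off by default) routes by vocabulary domain: a
binding to a code system whose codes live in a single OMOP domain pins the
matching table to rank 1 with rationale `vocabulary_domain` (or appends
it), never removing existing suggestions. Only unambiguous systems are
bundled: ATC → `drug_exposure`, LOINC → `measurement`, ICD-10 →
`condition_occurrence`.

The vocabulary inventory is a flat group-by over all bindings of all
scanned templates — one entry per distinct value set or code system with
usage counts and use sites, exported in a `source_code,
source_vocabulary, frequency` CSV shaped for Usagi intake.

## CDM catalogue

The OMOP CDM v5.4 target model (39 tables) ships as a flat CSV hand-derived
from the CDM specification, so no network access is ever needed. Field
lists are complete for the clinical and health-system tables the mapper
targets; vocabulary, era and economics tables carry their core columns
(no operation reads those fields).

## Project export

Every export writes two serializations from the same in-memory document:

* the primary `.json.gz` project in a GSON-style dialect modelled on the
  open-source ETL serialization of the Rabbit-In-a-Hat / WhiteRabbit
  lineage (`source`/`target` databases with tables and fields,
  `tableToTableMaps`, `tableMapToFieldToFieldMaps`). The exact dialect of
  any given Rabbit-In-a-Hat release cannot be pinned here, so this is an
  approximation of that family; unknown keys are preserved opaquely on
  load so round trips are lossless;
* a versioned native JSON sidecar (`format: cdarabbit-project`,
  `formatVersion: 1.0`) as the stable, documented fallback schema.

Source tables are named by template display name, disambiguated by a
short OID hash on collision; the full OID, level, class and all locators
travel in the table comment. Determinism is a hard contract: the creation
timestamp is injectable, gzip mtime is zeroed and the embedded filename
suppressed, so fixed inputs give byte-identical files and
export → load → export reproduces the first file exactly.

The scan workbook mirrors a profiling tool's overview sheet (one row per
template element, with datatype, cardinality and binding summary);
instance-statistics columns are zero because no instance data is profiled
— by design, this tool runs before such data is accessible.

## Synthetic fixtures

The generator emulates the structure of a national template repository:
`n_document` document templates, `n_section` sections, `n_entry` entries
(classes drawn from Observation, SubstanceAdministration, Supply, Act,
Procedure, Specimen), plus exactly one shared header template included at
root level by every document — so both containment and include semantics
are always exercised. Sections and entries are assigned round-robin to
keep every template reachable; `reuse_probability` and `contain_density`
add extra containment edges, producing templates with multiple locators.
Elements are drawn from a fixed pool of realistic CDA paths and HL7 V3
datatypes; coded elements get value-set or fixed-code bindings from
`vocab_pool`. `inject_cycle` adds a mutual entry→entry reference.
Defaults (2 documents, 4 sections, 6 entries — thirteen templates, the
scale of a small two-document national repository slice) keep full
pipeline runs well under a second, so the test suite and the acceptance
script run hundreds of them.

The manifest is produced from the same draw as the XML and records the
ground truth: template/element/reference counts, expected locators
(computed by an independent walk over the generator's own edge lists) and
the expected vocabulary inventory. Generated instances realize a document
template top-down: `minimal` fills only required paths, `all_optional`
fills every optional element and reference slot once; each instantiated
occurrence carries its `templateId` marker, as nationally deployed CDA
documents do. Cycle edges are unrolled at most once.

Locator verification evaluates each locator on an instance: *matched* if
some selected node carries the template's OID in a `templateId` child;
otherwise *not instantiated* if the containment chain is optional
somewhere (or belongs to a different document root), else *mismatch*.
The end-to-end property the suite enforces: over seeded random
repositories, an all-optional instance must match every locator of its
root — zero mismatches, zero unverified.

What the synthetic data does **not** emulate: clinically meaningful
content, schema-valid element ordering, Schematron conformance, realistic
vocabulary sizes, or instance-level heterogeneity. Passing tests
therefore demonstrate structural correctness of parsing, traversal,
locator algebra, mapping derivation and export — not fitness of the
default mapping table for any particular national repository, which
always needs review by the ETL designer.

## The bundled demonstration repository

`data/mini_repository.xml` is a frozen, hand-written *synthetic*
repository: two document templates (a physician discharge summary and a
laboratory report) expanding to 13 reachable templates across all four
levels, with LOINC- and ATC-like bindings and a reused observation entry.
All its OIDs are synthetic. It anchors the smoke tests: a scan yields 13
source tables, rank-1 suggestions covering 8 distinct CDM tables
(including `person`, `measurement`, `drug_exposure`), the
Patient → `person` and `administrativeGenderCode` →
`gender_source_value` arcs, and a byte-identical export round trip.

## Numerical and degenerate-input choices

* Empty repository: legal, zero templates plus a warning. No
  document-level templates: legal, empty root list plus a warning.
* Duplicate `(oid, effectiveDate)`: last definition wins with a warning;
  an error under `--strict`.
* Dangling references, cycles and locator truncation are warnings;
  `--strict` promotes them to errors.
* Unknown R-MIM class yields zero suggestions, never an error.
* Cycle reports are canonicalized by rotating each cycle to its smallest
  node key and sorting, so reports are deterministic.
* The scan path uses no randomness at all; only the fixture generators
  take seeds.

## Known limitations

* No instance-data profiling (frequencies, missingness): scan reports
  carry structure only.
* Cycles are reported, not resolved into finite expansions.
* Value sets are inventoried by identifier; member codes are not expanded.
* The prototype map and default rule table are reconstructions (see
  above) and should be tuned per deployment.
* The primary project dialect approximates an unpinned external reader;
  the native sidecar is the stable contract.
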