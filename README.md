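# cdarabbit

Derive OMOP CDM ETL design inputs directly from HL7 CDA Template
definitions — no patient-level documents required.

## The problem

Transforming CDA-based routine clinical data (the dominant document
standard in many national EHR systems) into the OMOP Common Data Model
requires a structural ETL design: which document parts feed which CDM
tables and fields. The standard OHDSI workflow profiles a relational
source with WhiteRabbit and designs the mapping in Rabbit-In-a-Hat — but
CDA sources are XML documents, not tables, and patient-level data is often
the last thing an ETL team gets access to.

CDA sources are, however, governed by **CDA Templates**: OID-identified
constraint definitions on the CDA R-MIM (HL7 V3's generic
clinical-document model) that prescribe structure, cardinalities and
terminology bindings per document type. `cdarabbit` scans a template
repository (ART-DECOR "decor" XML) instead of instance data:

* parses every template — metadata, level (document/header/section/entry),
  constrained elements with datatype, cardinality and vocabulary bindings;
* builds the include/contains dependency graph, walks it from the
  document-level templates, and **detects (but does not resolve) cyclic
  dependencies**;
* computes **locators** — every absolute XPath at which a template
  occurrence can appear in a conforming instance;
* resolves each template's **CDA R-MIM class** (Patient, Observation,
  SubstanceAdministration, …) and derives ranked **default mapping
  suggestions** into CDM v5.4 tables and fields from class semantics
  (e.g. Patient → `person`, `administrativeGenderCode` →
  `person.gender_source_value`; Observation → `measurement` with
  `observation` as the ranked alternative);
* inventories the **source vocabularies** (value sets and code systems)
  that will need terminology mapping, in a Usagi-shaped CSV;
* exports everything as a **Rabbit-In-a-Hat-style project file**
  (templates as source tables, elements as fields, rank-1 suggestions as
  arcs, locators and alternatives in comments) plus a scan workbook and
  CSV side outputs.

A synthetic-fixture module generates seeded decor repositories and
conformant CDA instances with a known ground truth, and verifies computed
locators against instances — the package's end-to-end correctness check.

## Worked example

The package bundles a frozen synthetic demonstration repository — two
document templates (physician discharge summary, laboratory report)
expanding to 13 reachable templates. Scan it:

```sh
cdarabbit -v scan \
    --repo src/cdarabbit/data/mini_repository.xml \
    --out-project project.json.gz \
    --out-inventory inventory.csv
```

```
INFO parsed 13 templates (0 warnings)
INFO graph: 13 nodes, 15 edges, 0 dangling
INFO scan roots: 1.2.40.0.34.999.1.1, 1.2.40.0.34.999.1.2
INFO traversal reached 13 templates
INFO computed 13 locators
INFO derived 40 mapping suggestions
INFO identified 7 source vocabularies
INFO wrote project file project.json.gz
INFO wrote vocabulary inventory inventory.csv
```

Both document-level templates were taken as scan roots; all 13 templates
they reference (directly or transitively) became source tables in the
project file. The 40 suggestions include, at rank 1, arcs into 8 distinct
CDM tables — among them `Patient → person` with
`hl7:administrativeGenderCode → gender_source_value`,
`Vital Signs Entry → measurement`, and `Medication Entry →
drug_exposure`. The vocabulary inventory lists the 7 value sets / code
systems bound in the templates with their usage frequencies:

```
source_code,source_vocabulary,frequency
2.16.840.1.113883.6.1,LOINC,5
1.2.40.0.34.999.10.1,AdministrativeGender,1
...
```

`project.json.gz` opens as an ETL specification (a versioned native JSON
sidecar is always written alongside); the locator of every template —
e.g. `/hl7:ClinicalDocument/hl7:recordTarget/hl7:patientRole/hl7:patient`
for the patient header — travels in the source-table comments for use in
the later ETL implementation.

The same things are available as a library:

```python
import cdarabbit as cr

repo = cr.parse_repository("templates.xml")
cr.resolve_all_rmim_classes(repo)
graph = cr.build_graph(repo)
roots = cr.find_document_roots(graph, repo)
locators = cr.compute_locators(graph, repo, roots)
print(cr.detect_cycles(graph).describe())
```

Other subcommands: `list-templates`, `cycles`, `cdm list-tables`,
`fixtures make-repo`, `fixtures make-instance`, and `verify` (check
computed locators against a CDA instance).

## Layout

```
src/cdarabbit/
  model.py           domain types (templates, elements, bindings, references)
  decor_parser.py    decor XML -> domain model; R-MIM class resolution
  template_graph.py  dependency graph, traversal, cycles, XPath locators
  cdm_catalog.py     bundled OMOP CDM v5.4 table/field catalogue
  default_mapper.py  R-MIM default mappings, vocabulary refinement, inventory
  project_export.py  project file (.json.gz + native sidecar), scan workbook
  fixtures.py        synthetic repositories/instances, locator verification
  cli.py             the `cdarabbit` command-line pipeline
  data/              CDM catalogue, rule tables, demo repository (all CSV/XML)
docs/methods.md      model, algorithms, design choices, limitations
```

See `docs/methods.md` for the full account of the parsing subset, the
locator algebra, the mapping rule table (a documented reconstruction),
and what the synthetic fixtures do and do not emulate.
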