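"""Dependency graph, traversal, cycle detection and locator computation."""

import random

import pytest

from cdarabbit import (
    TemplateId,
    build_graph,
    compute_locators,
    detect_cycles,
    find_document_roots,
    parse_repository,
    traverse_from_roots,
)
from cdarabbit.model import CdaRabbitError
from cdarabbit.template_graph import GraphEdge, TemplateGraph, locator_table_rows
from cdarabbit.model import ReferenceKind, TemplateReference

from conftest import make_decor


# -- independent oracles ---------------------------------------------------


def brute_force_simple_cycles(n_nodes, edges):
    """Enumerate all simple cycles by exhaustive DFS over simple paths,
    canonicalized by rotating each cycle to start at its smallest node."""
    adjacency = {i: sorted({b for a, b in edges if a == i}) for i in range(n_nodes)}
    found = set()

    def walk(start, node, path):
        for nxt in adjacency[node]:
            if nxt == start:
                pivot = path.index(min(path))
                found.add(tuple(path[pivot:] + path[:pivot]))
            elif nxt > start and nxt not in path:
                walk(start, nxt, path + [nxt])

    for start in range(n_nodes):
        walk(start, start, [start])
    return found


def brute_force_reachable(roots, edges):
    """Reachability by fixed-point iteration over the edge relation."""
    reached = set(roots)
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            if a in reached and b not in reached:
                reached.add(b)
                changed = True
    return reached


def make_graph(n_nodes, edges):
    """Assemble a TemplateGraph directly from an integer edge list."""
    ids = [TemplateId(f"1.2.{i}") for i in range(n_nodes)]
    graph = TemplateGraph(nodes=list(ids))
    for a, b in edges:
        ref = TemplateReference(
            kind=ReferenceKind.CONTAINS, target=ids[b], via_path="hl7:x"
        )
        graph.edges.append(GraphEdge(ids[a], ids[b], ref))
    return graph, ids


# -- build_graph -----------------------------------------------------------


def test_build_graph_counts_nodes_edges():
    body = """
    <template id="1.1.1" name="doc" statusCode="active">
      <classification type="cdadocumentlevel"/>
      <element name="hl7:ClinicalDocument" minimumMultiplicity="1" maximumMultiplicity="1">
        <element name="hl7:component" minimumMultiplicity="1" maximumMultiplicity="1">
          <element name="hl7:section" contains="1.1.2" minimumMultiplicity="1" maximumMultiplicity="1"/>
        </element>
        <element name="hl7:component" minimumMultiplicity="0" maximumMultiplicity="1">
          <element name="hl7:section" contains="1.1.3" minimumMultiplicity="0" maximumMultiplicity="1"/>
        </element>
      </element>
    </template>
    <template id="1.1.2" name="secA" statusCode="active">
      <classification type="cdasectionlevel"/>
      <element name="hl7:section" minimumMultiplicity="1" maximumMultiplicity="1">
        <element name="hl7:entry" minimumMultiplicity="0" maximumMultiplicity="1">
          <element name="hl7:observation" contains="1.1.4" minimumMultiplicity="0" maximumMultiplicity="1"/>
        </element>
      </element>
    </template>
    <template id="1.1.3" name="secB" statusCode="active">
      <classification type="cdasectionlevel"/>
      <element name="hl7:section" minimumMultiplicity="1" maximumMultiplicity="1"/>
    </template>
    <template id="1.1.4" name="entry1" statusCode="active">
      <classification type="cdaentrylevel"/>
      <element name="hl7:observation" minimumMultiplicity="1" maximumMultiplicity="1"/>
    </template>
    """
    repo = parse_repository(make_decor(body))
    graph = build_graph(repo)
    assert len(graph.nodes) == 4
    assert len(graph.edges) == 3
    assert graph.dangling == []


def test_unresolved_reference_goes_to_dangling_with_warning():
    body = """
    <template id="1.1.1" name="doc" statusCode="active">
      <element name="hl7:ClinicalDocument" minimumMultiplicity="1" maximumMultiplicity="1">
        <element name="hl7:section" contains="9.9.9" minimumMultiplicity="1" maximumMultiplicity="1"/>
      </element>
    </template>
    """
    repo = parse_repository(make_decor(body))
    graph = build_graph(repo)
    assert graph.edges == []
    assert [d.oid for d in graph.dangling] == ["9.9.9"]
    assert any("9.9.9" in w for w in graph.warnings)


def test_repository_without_references_has_no_edges():
    repo = parse_repository(
        make_decor('<template id="1.2.3" name="T" statusCode="active"/>')
    )
    assert build_graph(repo).edges == []


# -- roots and traversal ---------------------------------------------------


def test_find_document_roots_in_repository_order(demo_repo):
    graph = build_graph(demo_repo)
    roots = find_document_roots(graph, demo_repo)
    assert [r.oid for r in roots] == ["1.2.40.0.34.999.1.1", "1.2.40.0.34.999.1.2"]


def test_entry_only_repository_has_no_roots_and_warns():
    body = """
    <template id="1.2.3" name="E" statusCode="active">
      <classification type="cdaentrylevel"/>
      <element name="hl7:observation" minimumMultiplicity="1" maximumMultiplicity="1"/>
    </template>
    """
    repo = parse_repository(make_decor(body))
    graph = build_graph(repo)
    assert find_document_roots(graph, repo) == []
    assert any("document-level" in w for w in graph.warnings)


def test_traversal_is_preorder_and_reports_each_template_once():
    # doc -> secA -> entry1, doc -> secB -> entry1: entry1 appears once
    graph, ids = make_graph(4, [(0, 1), (1, 3), (0, 2), (2, 3)])
    order = traverse_from_roots(graph, [ids[0]])
    assert order == [ids[0], ids[1], ids[3], ids[2]]


def test_traversal_cuts_cycle_edges_and_terminates():
    graph, ids = make_graph(2, [(0, 1), (1, 0)])
    assert traverse_from_roots(graph, [ids[0]]) == [ids[0], ids[1]]


def test_unknown_root_raises_with_oid():
    graph, ids = make_graph(2, [(0, 1)])
    with pytest.raises(CdaRabbitError) as err:
        traverse_from_roots(graph, [TemplateId("9.9.9")])
    assert "9.9.9" in str(err.value)


def test_traversal_matches_reachability_oracle_on_random_graphs():
    rng = random.Random(2024)
    for _ in range(50):
        n = rng.randint(2, 10)
        edges = [
            (a, b)
            for a in range(n)
            for b in range(n)
            if a != b and rng.random() < 0.25
        ]
        graph, ids = make_graph(n, edges)
        roots = [ids[i] for i in range(n) if rng.random() < 0.4] or [ids[0]]
        order = traverse_from_roots(graph, roots)
        assert len(order) == len({t.oid for t in order})
        expected = brute_force_reachable({ids.index(r) for r in roots}, edges)
        assert {ids.index(t) for t in order} == expected


# -- cycles ----------------------------------------------------------------


def test_two_node_cycle_detected():
    graph, ids = make_graph(2, [(0, 1), (1, 0)])
    report = detect_cycles(graph)
    assert [[t.oid for t in c] for c in report.cycles] == [
        [ids[0].oid, ids[1].oid]
    ]
    assert "cycle" in report.describe()


def test_acyclic_chain_has_empty_report():
    graph, _ = make_graph(6, [(i, i + 1) for i in range(5)])
    report = detect_cycles(graph)
    assert report.cycles == [] and not report


def test_cycle_detection_equals_brute_force_on_random_graphs():
    rng = random.Random(99)
    for _ in range(60):
        n = rng.randint(2, 9)
        edges = [
            (a, b)
            for a in range(n)
            for b in range(n)
            if a != b and rng.random() < 0.3
        ]
        graph, ids = make_graph(n, edges)
        got = {
            tuple(int(t.oid.rsplit(".", 1)[-1]) for t in cyc)
            for cyc in detect_cycles(graph).cycles
        }
        assert got == brute_force_simple_cycles(n, edges)


# -- locators --------------------------------------------------------------


def test_locator_concatenates_via_paths_from_root_anchor(demo_repo):
    graph = build_graph(demo_repo)
    roots = find_document_roots(graph, demo_repo)
    locmap = compute_locators(graph, demo_repo, roots)
    section = locmap[("1.2.40.0.34.999.3.1", None)]
    assert [l.absolute_path for l in section] == [
        "/hl7:ClinicalDocument/hl7:component/hl7:structuredBody/hl7:component/hl7:section"
    ]
    (loc,) = section
    assert loc.provenance[0][0].oid == "1.2.40.0.34.999.1.1"
    assert loc.depth == 2


def test_template_contained_by_two_parents_gets_two_locators():
    graph, ids = make_graph(3, [(0, 2), (1, 2)])
    # make the two parents' slots differ so the paths do not coincide
    graph.edges[1] = GraphEdge(
        ids[1],
        ids[2],
        TemplateReference(kind=ReferenceKind.CONTAINS, target=ids[2], via_path="hl7:y"),
    )
    from cdarabbit.model import TemplateRepository, TemplateDefinition, TemplateLevel

    repo = TemplateRepository()
    for tid in ids:
        repo.add(
            TemplateDefinition(
                id=tid, level=TemplateLevel.DOCUMENT, root_element_name="hl7:ClinicalDocument"
            )
        )
    locmap = compute_locators(graph, repo, [ids[0], ids[1]])
    assert sorted(l.absolute_path for l in locmap[ids[2].key]) == [
        "/hl7:ClinicalDocument/hl7:x",
        "/hl7:ClinicalDocument/hl7:y",
    ]


def test_include_edges_inherit_parent_locator_unchanged(demo_repo):
    # the demo headers are contains-based; build an include case directly
    body = """
    <template id="1.1.1" name="doc" statusCode="active">
      <classification type="cdadocumentlevel"/>
      <include ref="1.1.2" minimumMultiplicity="1" maximumMultiplicity="1"/>
    </template>
    <template id="1.1.2" name="header" statusCode="active">
      <classification type="cdaheaderlevel"/>
      <element name="hl7:recordTarget" minimumMultiplicity="1" maximumMultiplicity="1"/>
    </template>
    """
    repo = parse_repository(make_decor(body))
    graph = build_graph(repo)
    locmap = compute_locators(graph, repo, find_document_roots(graph, repo))
    assert [l.absolute_path for l in locmap[("1.1.2", None)]] == [
        "/hl7:ClinicalDocument"
    ]


def test_cyclic_graph_locators_terminate_and_are_not_extended():
    graph, ids = make_graph(2, [(0, 1), (1, 0)])
    locmap = compute_locators(graph, docs_only_repo(ids), [ids[0]])
    assert len(locmap[ids[0].key]) == 1
    assert len(locmap[ids[1].key]) == 1
    assert any("cycle edge" in w for w in graph.warnings)


def docs_only_repo(ids):
    from cdarabbit.model import TemplateRepository, TemplateDefinition, TemplateLevel

    repo = TemplateRepository()
    for tid in ids:
        repo.add(
            TemplateDefinition(
                id=tid,
                level=TemplateLevel.DOCUMENT,
                root_element_name="hl7:ClinicalDocument",
            )
        )
    return repo


def test_depth_cap_truncates_with_warning():
    n = 20
    graph, ids = make_graph(n, [(i, i + 1) for i in range(n - 1)])
    repo = docs_only_repo(ids)
    locmap = compute_locators(graph, repo, [ids[0]], max_depth=5)
    assert ids[10].key not in locmap
    assert any("truncated" in w for w in graph.warnings)


def test_locator_computation_is_deterministic(demo_repo):
    graph = build_graph(demo_repo)
    roots = find_document_roots(graph, demo_repo)
    first = compute_locators(graph, demo_repo, roots)
    second = compute_locators(build_graph(demo_repo), demo_repo, roots)
    as_paths = lambda m: {k: [l.absolute_path for l in v] for k, v in m.items()}
    assert as_paths(first) == as_paths(second)


def test_predicate_locators_carry_template_id_filters(demo_repo):
    graph = build_graph(demo_repo)
    roots = find_document_roots(graph, demo_repo)
    locmap = compute_locators(graph, demo_repo, roots, predicates=True)
    (loc,) = locmap[("1.2.40.0.34.999.3.1", None)]
    assert "[hl7:templateId/@root='1.2.40.0.34.999.3.1']" in loc.absolute_path


def test_locator_table_rows_cover_every_locator(demo_repo):
    graph = build_graph(demo_repo)
    roots = find_document_roots(graph, demo_repo)
    locmap = compute_locators(graph, demo_repo, roots)
    rows = locator_table_rows(locmap, demo_repo)
    assert len(rows) == sum(len(v) for v in locmap.values())
    assert all(len(r) == 4 for r in rows)
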