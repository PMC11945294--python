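"""Template dependency graph, traversal, cycle detection, XPath locators.

Templates reference each other through *include* and *contains* arcs; the
resulting directed graph is walked from the document-level templates to
find everything that can occur in an instance of those document types, and
to compute, for every reachable template, all absolute XPath locations at
which an occurrence can appear inside a CDA document.

Cyclic template dependencies are legal under the templating standard; they
are detected and reported here but never expanded -- traversal and locator
computation cut the edge that would close a cycle and emit a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import (
    CdaRabbitError,
    ReferenceKind,
    TemplateDefinition,
    TemplateId,
    TemplateLevel,
    TemplateReference,
    TemplateRepository,
)

Key = tuple[str, Optional[str]]


@dataclass
class GraphEdge:
    source: TemplateId
    target: TemplateId  # resolved id of the target definition
    reference: TemplateReference


@dataclass
class TemplateGraph:
    """Directed include/contains graph over a parsed repository."""

    nodes: list[TemplateId] = field(default_factory=list)
    edges: list[GraphEdge] = field(default_factory=list)
    dangling: list[TemplateId] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def node_keys(self) -> set[Key]:
        return {n.key for n in self.nodes}

    def out_edges(self, node: TemplateId) -> list[GraphEdge]:
        return [e for e in self.edges if e.source.key == node.key]


@dataclass
class Locator:
    """An absolute XPath at which a template occurrence can appear.

    ``provenance`` records the containment chain from a document-level root
    to this template as (template id, via_path) hops; the absolute path is
    the root anchor joined with every non-empty via_path in order.
    """

    template: TemplateId
    absolute_path: str
    provenance: list[tuple[TemplateId, str]] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.provenance)


@dataclass
class CycleReport:
    """Simple cycles among include/contains edges, deduplicated up to rotation."""

    cycles: list[list[TemplateId]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.cycles)

    def describe(self) -> str:
        if not self.cycles:
            return "no cyclic template dependencies"
        lines = []
        for cyc in self.cycles:
            chain = " -> ".join(t.oid for t in cyc) + f" -> {cyc[0].oid}"
            lines.append(f"cycle: {chain}")
        return "\n".join(lines)


def build_graph(repository: TemplateRepository) -> TemplateGraph:
    """One node per template, one edge per resolvable include/contains
    reference; unresolved targets are recorded in ``dangling``, never
    silently dropped."""
    graph = TemplateGraph()
    graph.nodes = [t.id for t in repository]
    for template in repository:
        for ref in template.containment_references():
            target_def = repository.get(ref.target)
            if target_def is None:
                graph.dangling.append(ref.target)
                graph.warnings.append(
                    f"{template.id.oid}: unresolved {ref.kind.value} "
                    f"reference to {ref.target.oid}"
                )
                continue
            graph.edges.append(GraphEdge(template.id, target_def.id, ref))
    return graph


def find_document_roots(
    graph: TemplateGraph, repository: TemplateRepository
) -> list[TemplateId]:
    """All document-level templates, in repository (document) order."""
    roots = [t.id for t in repository if t.level is TemplateLevel.DOCUMENT]
    if not roots:
        graph.warnings.append("repository has no document-level templates")
    return roots


def traverse_from_roots(
    graph: TemplateGraph, roots: list[TemplateId]
) -> list[TemplateId]:
    """Depth-first preorder over include/contains edges from each root.

    Every template is reported once (first encounter wins); edges that
    would revisit an already-seen template are not expanded, so traversal
    terminates on cyclic graphs.
    """
    keys = graph.node_keys()
    for root in roots:
        if root.key not in keys:
            raise CdaRabbitError(f"scan root {root.oid} is not in the template graph")
    order: list[TemplateId] = []
    seen: set[Key] = set()

    def visit(node: TemplateId) -> None:
        if node.key in seen:
            return
        seen.add(node.key)
        order.append(node)
        for edge in graph.out_edges(node):
            visit(edge.target)

    for root in roots:
        visit(root)
    return order


def detect_cycles(graph: TemplateGraph) -> CycleReport:
    """Every simple cycle among include/contains edges.

    Cycles are canonicalized (rotated to start at their smallest node key)
    and sorted, so the report is deterministic and deduplicated.
    """
    g = nx.DiGraph()
    g.add_nodes_from(n.key for n in graph.nodes)
    by_key = {n.key: n for n in graph.nodes}
    for e in graph.edges:
        g.add_edge(e.source.key, e.target.key)
    cycles = []
    for cyc in nx.simple_cycles(g):
        pivot = min(range(len(cyc)), key=lambda i: cyc[i])
        rotated = cyc[pivot:] + cyc[:pivot]
        cycles.append(rotated)
    cycles.sort(key=lambda c: (len(c), c))
    return CycleReport(cycles=[[by_key[k] for k in c] for c in cycles])


def compute_locators(
    graph: TemplateGraph,
    repository: TemplateRepository,
    roots: list[TemplateId],
    max_depth: int = 12,
    max_locators_per_template: int = 64,
    predicates: bool = False,
) -> dict[Key, list[Locator]]:
    """All absolute XPath locations for every template reachable from roots.

    A root template is anchored at ``/hl7:ClinicalDocument``.  A template
    reached over an edge gets, for each locator ``L`` of its parent,
    ``L + "/" + via_path`` (include edges with empty via_path inherit ``L``
    unchanged).  Locators are deduplicated on absolute path per template;
    paths through cycle back-edges are never extended; the depth and count
    caps guarantee termination and emit a warning when they truncate.

    With ``predicates=True`` each hop is narrowed by a
    ``[hl7:templateId/@root='...']`` predicate on its final step, which
    makes locators selective at the cost of portability.
    """
    locmap: dict[Key, list[Locator]] = {}
    seen_paths: dict[Key, set[str]] = {}
    truncated: set[str] = set()

    def predicate_for(tid: TemplateId) -> str:
        return f"[hl7:templateId/@root='{tid.oid}']" if predicates else ""

    def add(loc: Locator) -> bool:
        key = loc.template.key
        paths = seen_paths.setdefault(key, set())
        if loc.absolute_path in paths:
            return False
        if len(paths) >= max_locators_per_template:
            truncated.add(loc.template.oid)
            return False
        paths.add(loc.absolute_path)
        locmap.setdefault(key, []).append(loc)
        return True

    def expand(node: TemplateId, loc: Locator, chain: set[Key]) -> None:
        if len(loc.provenance) >= max_depth:
            truncated.add(node.oid)
            return
        for edge in graph.out_edges(node):
            if edge.target.key in chain:
                graph.warnings.append(
                    f"cycle edge {node.oid} -> {edge.target.oid} not expanded"
                )
                continue
            via = edge.reference.via_path
            if via:
                child_path = f"{loc.absolute_path}/{via}{predicate_for(edge.target)}"
            else:
                child_path = loc.absolute_path
            child_loc = Locator(
                template=edge.target,
                absolute_path=child_path,
                provenance=loc.provenance + [(edge.target, via)],
            )
            if add(child_loc):
                expand(edge.target, child_loc, chain | {edge.target.key})

    keys = graph.node_keys()
    for root in roots:
        if root.key not in keys:
            raise CdaRabbitError(f"locator root {root.oid} is not in the graph")
        root_def = repository.get(root)
        anchor_name = "hl7:ClinicalDocument"
        if root_def is not None and root_def.root_element_name:
            anchor_name = root_def.root_element_name
        anchor = f"/{anchor_name}{predicate_for(root)}"
        root_loc = Locator(template=root, absolute_path=anchor, provenance=[(root, "")])
        if add(root_loc):
            expand(root, root_loc, {root.key})
    for oid in sorted(truncated):
        graph.warnings.append(f"locator set for {oid} truncated by caps")
    return locmap


def locator_table_rows(
    locmap: dict[Key, list[Locator]], repository: TemplateRepository
) -> list[tuple[str, str, str, int]]:
    """Flat (oid, display name, absolute_path, depth) rows for CSV export."""
    rows = []
    for key in locmap:
        template = repository.templates.get(key)
        name = template.display_name if template else key[0]
        for loc in locmap[key]:
            rows.append((loc.template.oid, name, loc.absolute_path, loc.depth))
    return rows
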