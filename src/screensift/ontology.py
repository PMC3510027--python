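"""Gene Ontology handling: OBO parsing, GAF annotations, true-path propagation.

Only the ``is_a`` relation defines the term DAG here: term *level* is the
shortest is_a path length from the namespace root (root = 0), and the
true-path rule states that a gene annotated to a term is implicitly
annotated to every is_a ancestor of that term.  Other relations
(part_of, regulates, ...) present in an OBO file are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    """Raised on structurally invalid ontologies (cycles, missing roots)."""


@dataclass
class GeneOntology:
    """A DAG of ontology terms connected by is_a edges (child -> parent).

    Attributes
    ----------
    graph : nx.DiGraph
        is_a-only graph, edges directed child -> parent.
    names : dict
        term id -> human-readable name.
    namespaces : dict
        term id -> namespace (e.g. biological_process).
    roots : dict
        namespace -> root term id (the unique term with no is_a parent).
    alt_ids : dict
        secondary id -> canonical id.
    """

    graph: nx.DiGraph
    names: dict[str, str]
    namespaces: dict[str, str]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    _levels: dict[str, int] = field(default_factory=dict, repr=False)

    def canonical(self, term: str) -> str:
        """Resolve an alt_id to its canonical term id (identity otherwise)."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.canonical(term) in self.graph

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(self.canonical(term)))

    def ancestors(self, term: str, inclusive: bool = True) -> set[str]:
        """All is_a ancestors of a term (inclusive of the term by default)."""
        term = self.canonical(term)
        anc = nx.descendants(self.graph, term)
        if inclusive:
            anc = anc | {term}
        return anc

    def term_level(self, term: str) -> int:
        """Shortest is_a distance from the namespace root; root = 0."""
        term = self.canonical(term)
        if term not in self._levels:
            ns = self.namespaces.get(term)
            root = self.roots.get(ns)
            if root is None:
                raise OntologyError(f"no root for namespace {ns!r}")
            try:
                self._levels[term] = nx.shortest_path_length(self.graph, term, root)
            except nx.NetworkXNoPath:
                raise OntologyError(f"term {term} unreachable from root {root}")
        return self._levels[term]


def _build_ontology(graph: nx.DiGraph, names, namespaces, alt_ids) -> GeneOntology:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyError(f"is_a cycle detected: {cycle}")
    roots: dict[str, str] = {}
    for node in graph.nodes:
        if graph.out_degree(node) == 0:
            ns = namespaces.get(node, "")
            if ns in roots:
                raise OntologyError(
                    f"namespace {ns!r} has multiple roots: {roots[ns]}, {node}"
                )
            roots[ns] = node
    if not roots:
        raise OntologyError("ontology has no root term")
    return GeneOntology(graph, names, namespaces, roots, alt_ids)


def parse_obo(path) -> GeneOntology:
    """Parse an OBO 1.2 ontology into a :class:`GeneOntology`.

    Obsolete terms are dropped; alt_ids are mapped to canonical ids.
    Only is_a edges enter the DAG.
    """
    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    graph.add_nodes_from(multigraph.nodes)
    for term, data in multigraph.nodes(data=True):
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "")
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    return _build_ontology(graph, names, namespaces, alt_ids)


def parse_gaf(path) -> dict[str, set[str]]:
    """Parse a GAF 2.x annotation file into gene -> set of direct term ids.

    Column 2 (1-based) is the gene id, column 5 the term id, column 4 the
    qualifier; rows with a NOT qualifier are excluded per GAF semantics.
    """
    annots: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise OntologyError(
                    f"GAF line {lineno}: expected >= 15 columns, got {len(cols)}"
                )
            gene, qualifier, term = cols[1], cols[3], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            annots.setdefault(gene, set()).add(term)
    return annots


def propagate(dag: GeneOntology, annots: dict[str, set[str]]) -> dict[str, set[str]]:
    """True-path closure: each gene's terms unioned with all their ancestors.

    Annotations to terms absent from the DAG are skipped with a warning.
    """
    out: dict[str, set[str]] = {}
    for gene, terms in annots.items():
        closed: set[str] = set()
        for term in terms:
            if term not in dag:
                logger.warning("annotation of %s to unknown term %s skipped", gene, term)
                continue
            closed |= dag.ancestors(term, inclusive=True)
        if closed:
            out[gene] = closed
    return out


def term_level(dag: GeneOntology, term: str) -> int:
    """Module-level convenience for :meth:`GeneOntology.term_level`."""
    return dag.term_level(term)
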