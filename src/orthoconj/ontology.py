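"""Gene Ontology loading, annotation parsing, and term propagation.

Protein function is represented as a set of ontology terms.  Because the
ontology is a DAG in which a term implies all of its ancestors, per-protein
term sets are *propagated*: every annotated term contributes itself plus all
ancestors up to, but excluding, the namespace root.  The Biological Process
and Molecular Function namespaces are always handled independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import obonet

log = logging.getLogger(__name__)

#: Curated evidence codes admitted to the analysis: the five experimental
#: codes plus traceable author statement and curator inference.
ALLOWED_EVIDENCE_CODES = frozenset({"IDA", "IEP", "IGI", "IMP", "IPI", "TAS", "IC"})

#: Edge relations followed during propagation (GO convention).
DEFAULT_RELATIONS = ("is_a", "part_of")

NAMESPACES = ("biological_process", "molecular_function")


@dataclass
class OntologyDAG:
    """A single-namespace ontology DAG.

    ``graph`` stores child -> parent edges restricted to the configured
    relation kinds; ``root`` is the unique term with no outgoing edge.
    """

    graph: nx.DiGraph
    root: str
    namespace: str
    relations: tuple[str, ...] = DEFAULT_RELATIONS

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by following child->parent edges."""
        return nx.descendants(self.graph, term)


@dataclass
class AnnotationRecord:
    """One curated annotation line: a protein assigned a term with provenance."""

    protein_id: str
    term_id: str
    evidence_code: str
    publication_ids: frozenset[str]
    species: str

    def __post_init__(self) -> None:
        if self.evidence_code not in ALLOWED_EVIDENCE_CODES:
            raise ValueError(
                f"evidence code {self.evidence_code!r} not in allowed set "
                f"{sorted(ALLOWED_EVIDENCE_CODES)}"
            )


@dataclass
class AnnotationSet:
    """The propagated term set T(p) of a protein (root excluded)."""

    protein_id: str
    terms: frozenset[str]
    namespace: str


class OntologyError(ValueError):
    pass


def load_obo(
    path,
    namespace: str = "biological_process",
    relations: tuple[str, ...] = DEFAULT_RELATIONS,
) -> OntologyDAG:
    """Load one namespace of an OBO 1.2 ontology as a validated DAG.

    Obsolete terms are dropped (obonet's default), edges are restricted to
    ``relations``, and the result is checked for acyclicity, a unique root
    and full root-connectivity.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}; expected one of {NAMESPACES}")
    multigraph = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        if data.get("namespace", "biological_process") == namespace:
            g.add_node(node)
    for child, parent, rel in multigraph.edges(keys=True):
        if rel in relations and child in g and parent in g:
            g.add_edge(child, parent, relation=rel)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"ontology contains a cycle: {cycle}")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise OntologyError(
            f"namespace {namespace!r} must have exactly one root; found {sorted(roots)}"
        )
    root = roots[0]
    dag = OntologyDAG(graph=g, root=root, namespace=namespace, relations=tuple(relations))
    disconnected = [t for t in g.nodes if t != root and root not in dag.ancestors(t)]
    if disconnected:
        raise OntologyError(f"terms with no path to root {root}: {sorted(disconnected)[:5]}")
    return dag


def read_gaf(path) -> list[AnnotationRecord]:
    """Read a GAF-like TSV: protein_id, species, term_id, evidence_code, pubmed_ids.

    ``pubmed_ids`` is a semicolon-separated list.  Lines starting with ``!``
    or ``#`` are comments.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed annotation line (need 5 columns): {line!r}")
            protein_id, species, term_id, evidence, pubs = fields[:5]
            records.append(
                AnnotationRecord(
                    protein_id=protein_id,
                    term_id=term_id,
                    evidence_code=evidence,
                    publication_ids=frozenset(p for p in pubs.split(";") if p),
                    species=species,
                )
            )
    return records


def propagate_terms(terms, dag: OntologyDAG) -> frozenset[str]:
    """Union of ``terms`` with all their ancestors, minus the root."""
    out: set[str] = set()
    for t in terms:
        out.add(t)
        out |= dag.ancestors(t)
    out.discard(dag.root)
    return frozenset(out)


def propagate_annotations(
    records, dag: OntologyDAG
) -> dict[str, AnnotationSet]:
    """Propagate per-protein annotations toward the root (root excluded).

    Records whose term is unknown to the DAG are skipped with a logged
    warning; proteins whose propagated set comes out empty (annotated only
    with the root) are excluded from the result.
    """
    by_protein: dict[str, set[str]] = {}
    skipped = 0
    for rec in records:
        if rec.term_id not in dag:
            skipped += 1
            continue
        by_protein.setdefault(rec.protein_id, set()).add(rec.term_id)
    if skipped:
        log.warning("skipped %d annotation records with terms unknown to the %s DAG",
                    skipped, dag.namespace)
    out = {}
    for protein, terms in by_protein.items():
        propagated = propagate_terms(terms, dag)
        if propagated:
            out[protein] = AnnotationSet(protein_id=protein, terms=propagated,
                                         namespace=dag.namespace)
    return out


def term_depths(dag: OntologyDAG, path: str = "shortest") -> dict[str, int]:
    """Depth of every term as the distance from the root.

    ``path='shortest'`` (default) is BFS distance; ``path='longest'`` is the
    longest root-to-term path, computed over the topological order.  The
    root has depth 0.
    """
    rev = dag.graph.reverse(copy=False)  # parent -> child
    if path == "shortest":
        return dict(nx.single_source_shortest_path_length(rev, dag.root))
    if path == "longest":
        depth = {dag.root: 0}
        for node in nx.topological_sort(rev):
            for child in rev.successors(node):
                d = depth[node] + 1
                if d > depth.get(child, -1):
                    depth[child] = d
        return depth
    raise ValueError(f"path must be 'shortest' or 'longest', got {path!r}")


def term_depth(dag: OntologyDAG, term: str, path: str = "shortest") -> int:
    """Distance from the root to ``term`` (0 for the root itself)."""
    if term not in dag:
        raise KeyError(term)
    return term_depths(dag, path=path)[term]
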