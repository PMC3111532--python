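"""Gene-tree parsing and homolog-pair classification.

Every unordered pair of genes in a family tree is assigned one of five
evolutionary classes, determined by the event (speciation or duplication) at
the pair's last common ancestor and by the species content of that node's
subtree:

* ``ortholog_1to1`` — cross-species, speciation LCA, no duplication on
  either path from the LCA down to the leaves;
* ``ortholog_1toMany_or_Many`` — cross-species, speciation LCA, at least one
  duplication below it on a path to a member of the pair;
* ``inparalog`` — same-species, duplication LCA whose entire subtree
  contains a single species (the duplication postdates the species split);
* ``within_species_outparalog`` — same-species pair whose duplication LCA
  subtree spans both species (the duplication predates the split);
* ``between_species_outparalog`` — cross-species, duplication LCA.

A cross-species pair whose duplication LCA has species-disjoint child
subtrees is additionally flagged *apparent*: such "duplications" usually
reflect tree error (or reciprocal gene loss), and the pairs are by default
merged into the 1:1 ortholog class, mirroring how orthology databases treat
"apparent ortholog 1:1" calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import dendropy

ORTHOLOG_1TO1 = "ortholog_1to1"
ORTHOLOG_MANY = "ortholog_1toMany_or_Many"
INPARALOG = "inparalog"
WS_OUTPARALOG = "within_species_outparalog"
BS_OUTPARALOG = "between_species_outparalog"

ORTHOLOG_CLASSES = (ORTHOLOG_1TO1, ORTHOLOG_MANY)
PARALOG_CLASSES = (INPARALOG, WS_OUTPARALOG, BS_OUTPARALOG)
WITHIN_SPECIES_CLASSES = (INPARALOG, WS_OUTPARALOG)
ALL_CLASSES = ORTHOLOG_CLASSES + PARALOG_CLASSES

SPECIATION = "speciation"
DUPLICATION = "duplication"
UNLABELED = "unlabeled"

_NHX_D = re.compile(r"&&NHX[^\]]*?:?D=([YN])", re.IGNORECASE)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    species: str
    chromosome: str


@dataclass(frozen=True)
class HomologPair:
    """An unordered homologous gene pair with its evolutionary class."""

    gene_a: str
    gene_b: str
    cls: str
    family_id: str
    apparent: bool = False

    def __post_init__(self):
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)


class TreeError(ValueError):
    pass


def read_gene_table(path) -> dict[str, GeneRecord]:
    """Gene metadata TSV with columns gene_id, species, chromosome."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gene_id, species, chromosome = line.split("\t")[:3]
            table[gene_id] = GeneRecord(gene_id, species, chromosome)
    return table


def parse_gene_tree(newick_text: str, gene_table: dict[str, GeneRecord]) -> dendropy.Tree:
    """Parse one Newick tree with NHX-style ``D=Y|N`` duplication tags.

    Leaves get a ``gene`` attribute (their :class:`GeneRecord`); internal
    nodes get an ``event`` attribute decoded from the tag, or ``unlabeled``
    when no tag is present.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    for node in tree:
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_")
            if name not in gene_table:
                raise TreeError(f"leaf {name!r} not found in the gene table")
            node.gene = gene_table[name]
            node.event = None
        else:
            node.event = UNLABELED
            for comment in node.comments:
                m = _NHX_D.search(comment)
                if m:
                    node.event = DUPLICATION if m.group(1).upper() == "Y" else SPECIATION
    return tree


def read_gene_trees(path, gene_table) -> list[dendropy.Tree]:
    """One Newick tree per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_gene_tree(line, gene_table))
    return trees


def _species_below(node) -> set[str]:
    if not hasattr(node, "_species_below"):
        if node.is_leaf():
            node._species_below = frozenset({node.gene.species})
        else:
            s = set()
            for c in node.child_nodes():
                s |= _species_below(c)
            node._species_below = frozenset(s)
    return node._species_below


def label_events_species_overlap(tree, force: bool = False):
    """Fill in event labels by the species-overlap rule.

    A node is a duplication iff at least two of its child subtrees share a
    species; otherwise it is a speciation.  Existing tags win unless
    ``force`` relabels everything.
    """
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.event != UNLABELED and not force:
            continue
        children = node.child_nodes()
        seen: set[str] = set()
        event = SPECIATION
        for c in children:
            sub = _species_below(c)
            if seen & sub:
                event = DUPLICATION
                break
            seen |= sub
        node.event = event
    return tree


def _path_has_duplication(leaf, lca) -> bool:
    """True if any internal node strictly between ``lca`` and ``leaf`` is a duplication."""
    node = leaf.parent_node
    while node is not None and node is not lca:
        if node.event == DUPLICATION:
            return True
        node = node.parent_node
    return False


def classify_homolog_pairs(tree, family_id: str = "") -> list[HomologPair]:
    """Classify every unordered leaf pair of an event-labeled gene tree."""
    leaves = list(tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.event in (UNLABELED, None):
            raise TreeError(
                "tree has unlabeled internal nodes; run label_events_species_overlap first"
            )
    # ancestor chains for LCA lookup without repeated full-tree scans
    depth = {}
    for node in tree.preorder_node_iter():
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1

    def lca(u, v):
        while u is not v:
            if depth[id(u)] >= depth[id(v)]:
                u = u.parent_node
            else:
                v = v.parent_node
        return u

    pairs = []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            anc = lca(a, b)
            same_species = a.gene.species == b.gene.species
            dup_free = not (_path_has_duplication(a, anc) or _path_has_duplication(b, anc))
            if anc.event == SPECIATION:
                if same_species:
                    # inconsistent tagging: a speciation LCA implies the copies
                    # diverged no later than the species split
                    cls, apparent = WS_OUTPARALOG, False
                else:
                    cls = ORTHOLOG_1TO1 if dup_free else ORTHOLOG_MANY
                    apparent = False
            else:  # duplication LCA
                if same_species:
                    n_species = len(_species_below(anc))
                    cls = INPARALOG if n_species == 1 else WS_OUTPARALOG
                    apparent = False
                else:
                    cls = BS_OUTPARALOG
                    # species-disjoint children make the duplication dubious
                    child_sets = [_species_below(c) for c in anc.child_nodes()]
                    disjoint = all(
                        not (child_sets[i] & child_sets[j])
                        for i in range(len(child_sets))
                        for j in range(i + 1, len(child_sets))
                    )
                    apparent = disjoint and dup_free
            pairs.append(HomologPair(a.gene.gene_id, b.gene.gene_id, cls,
                                     family_id, apparent))
    return pairs


def treat_apparent_orthologs(pairs, merge: bool = True) -> list[HomologPair]:
    """Merge *apparent* 1:1 orthologs into the 1:1 ortholog class.

    With ``merge`` off, apparent pairs are removed entirely (they then
    contribute to neither the ortholog nor the outparalog analyses).
    """
    out = []
    for p in pairs:
        if p.apparent and p.cls == BS_OUTPARALOG:
            if merge:
                out.append(replace(p, cls=ORTHOLOG_1TO1))
        else:
            out.append(p)
    return out
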