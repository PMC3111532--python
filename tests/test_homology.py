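"""Gene-tree event labeling and pair classification vs a brute-force oracle."""

import itertools

import numpy as np
import pytest

from orthoconj.homology import (BS_OUTPARALOG, DUPLICATION, INPARALOG,
                                ORTHOLOG_1TO1, ORTHOLOG_MANY, SPECIATION,
                                UNLABELED, WS_OUTPARALOG,
                                TreeError, classify_homolog_pairs,
                                label_events_species_overlap, parse_gene_tree,
                                treat_apparent_orthologs)

from conftest import gene_table


def classes_of(pairs):
    return {(p.gene_a, p.gene_b): p.cls for p in pairs}


class TestParsing:
    def test_tag_decoding(self, two_species_genes):
        t = parse_gene_tree("(H1:1,M1:1):0[&&NHX:D=N];", two_species_genes)
        assert t.seed_node.event == SPECIATION
        t = parse_gene_tree("(H1:1,H2:1):0[&&NHX:D=Y];", two_species_genes)
        assert t.seed_node.event == DUPLICATION

    def test_untagged_node_unlabeled_then_overlap_resolves(self, two_species_genes):
        t = parse_gene_tree("(H1:1,H2:1);", two_species_genes)
        assert t.seed_node.event == UNLABELED
        label_events_species_overlap(t)
        assert t.seed_node.event == DUPLICATION

    def test_unknown_leaf_is_hard_error(self, two_species_genes):
        with pytest.raises(TreeError, match="ZZ"):
            parse_gene_tree("(ZZ:1,M1:1);", two_species_genes)

    def test_malformed_newick_is_hard_error(self, two_species_genes):
        with pytest.raises(TreeError):
            parse_gene_tree("((H1,M1;", two_species_genes)


class TestSpeciesOverlap:
    def test_disjoint_children_speciation(self, two_species_genes):
        t = parse_gene_tree("((H1,H2),M1);", two_species_genes)
        label_events_species_overlap(t)
        assert t.seed_node.event == SPECIATION

    def test_overlapping_children_duplication(self, two_species_genes):
        t = parse_gene_tree("((H1,M1),H2);", two_species_genes)
        label_events_species_overlap(t)
        assert t.seed_node.event == DUPLICATION

    def test_two_cherries_root_is_duplication(self, two_species_genes):
        t = parse_gene_tree("((H1,M1),(H2,M2));", two_species_genes)
        label_events_species_overlap(t)
        events = [n.event for n in t.preorder_internal_node_iter()]
        assert events == [DUPLICATION, SPECIATION, SPECIATION]

    def test_tags_win_unless_forced(self, two_species_genes):
        t = parse_gene_tree("((H1,H2):1[&&NHX:D=N],M1);", two_species_genes)
        label_events_species_overlap(t)
        inner = [n for n in t.preorder_internal_node_iter()][1]
        assert inner.event == SPECIATION  # tag kept
        label_events_species_overlap(t, force=True)
        assert inner.event == DUPLICATION


class TestHomologyDefinitions:
    """The canonical one-to-many and two-pair topologies."""

    def test_one_to_many_family(self, one_to_many_tree, two_species_genes):
        t = parse_gene_tree(one_to_many_tree, two_species_genes)
        cls = classes_of(classify_homolog_pairs(t))
        assert cls[("H1", "M1")] == ORTHOLOG_MANY
        assert cls[("H2", "M1")] == ORTHOLOG_MANY
        assert cls[("H3", "M1")] == ORTHOLOG_MANY
        assert cls[("H1", "H2")] == INPARALOG
        assert cls[("H1", "H3")] == INPARALOG
        assert cls[("M1", "M2")] == WS_OUTPARALOG
        assert cls[("H4", "M1")] == BS_OUTPARALOG
        assert cls[("H1", "H4")] == WS_OUTPARALOG  # pre-split dup, same species

    def test_two_one_to_one_pairs(self, two_pairs_tree, two_species_genes):
        t = parse_gene_tree(two_pairs_tree, two_species_genes)
        cls = classes_of(classify_homolog_pairs(t))
        assert cls[("H1", "M1")] == ORTHOLOG_1TO1
        assert cls[("H2", "M2")] == ORTHOLOG_1TO1
        assert cls[("H2", "M1")] == BS_OUTPARALOG
        assert cls[("H1", "M2")] == BS_OUTPARALOG
        assert cls[("H1", "H2")] == WS_OUTPARALOG
        assert cls[("M1", "M2")] == WS_OUTPARALOG


class TestApparentOrthologs:
    def test_merge_flag_on_and_off(self, two_species_genes):
        # a duplication whose children are species-disjoint is dubious
        t = parse_gene_tree("(H1:1,M1:1):0[&&NHX:D=Y];", two_species_genes)
        pairs = classify_homolog_pairs(t)
        assert pairs[0].cls == BS_OUTPARALOG and pairs[0].apparent
        merged = treat_apparent_orthologs(pairs, merge=True)
        assert merged[0].cls == ORTHOLOG_1TO1
        dropped = treat_apparent_orthologs(pairs, merge=False)
        assert dropped == []

    def test_non_apparent_pairs_unchanged(self, two_pairs_tree, two_species_genes):
        t = parse_gene_tree(two_pairs_tree, two_species_genes)
        pairs = classify_homolog_pairs(t)
        assert not any(p.apparent for p in pairs)
        assert treat_apparent_orthologs(pairs, merge=True) == pairs
        assert treat_apparent_orthologs(pairs, merge=False) == pairs


# ---------------------------------------------------------------------------
# brute-force oracle: independent nested-tuple tree representation
# ---------------------------------------------------------------------------

def oracle_classify(tree, species):
    """Classify all pairs of a nested-tuple tree.

    ``tree`` is a leaf name or (event, left, right); ``species`` maps leaf
    to species.  Per pair: walk every subtree, find the smallest one
    containing both leaves, then apply the class rules from the species
    content of that subtree and of the paths below it.
    """
    def leaves(t):
        return [t] if isinstance(t, str) else leaves(t[1]) + leaves(t[2])

    def subtrees(t):
        yield t
        if not isinstance(t, str):
            yield from subtrees(t[1])
            yield from subtrees(t[2])

    def dup_between(t, leaf):
        """Any duplication strictly below t on the path to leaf."""
        if isinstance(t, str):
            return False
        side = t[1] if leaf in leaves(t[1]) else t[2]
        if isinstance(side, str):
            return False
        return (side[0] == "D") or dup_between(side, leaf)

    out = {}
    all_leaves = leaves(tree)
    for a, b in itertools.combinations(all_leaves, 2):
        lca = None
        for sub in subtrees(tree):
            ls = leaves(sub)
            if a in ls and b in ls and (lca is None or len(ls) < len(leaves(lca))):
                lca = sub
        event = lca[0]
        same = species[a] == species[b]
        if event == "S":
            if same:
                cls = WS_OUTPARALOG
            else:
                nodup = not (dup_between(lca, a) or dup_between(lca, b))
                cls = ORTHOLOG_1TO1 if nodup else ORTHOLOG_MANY
        elif same:
            sub_species = {species[x] for x in leaves(lca)}
            cls = INPARALOG if len(sub_species) == 1 else WS_OUTPARALOG
        else:
            cls = BS_OUTPARALOG
        key = (a, b) if a < b else (b, a)
        out[key] = cls
    return out


def random_tuple_tree(n_leaves, rng):
    nodes = [f"g{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        event = "D" if rng.random() < 0.5 else "S"
        nodes.append((event, left, right))
    return nodes[0]


def tuple_to_newick(t):
    if isinstance(t, str):
        return t
    tag = "Y" if t[0] == "D" else "N"
    return f"({tuple_to_newick(t[1])},{tuple_to_newick(t[2])}):1[&&NHX:D={tag}]"


class TestClassificationOracle:
    def test_exhaustive_small_trees(self):
        """All shapes x species assignments x event labelings, 4 leaves."""
        leaves = ["g0", "g1", "g2", "g3"]

        def all_shapes(items):
            if len(items) == 1:
                yield items[0]
                return
            n = len(items)
            seen = set()
            for k in range(1, n // 2 + 1):
                for combo in itertools.combinations(range(n), k):
                    rest = tuple(i for i in range(n) if i not in combo)
                    if k == n - k and combo > rest:
                        continue
                    if (combo, rest) in seen:
                        continue
                    seen.add((combo, rest))
                    for l in all_shapes([items[i] for i in combo]):
                        for r in all_shapes([items[i] for i in rest]):
                            yield ("?", l, r)

        def label_events(t, labels):
            if isinstance(t, str):
                return t
            return (labels.pop(0), label_events(t[1], labels),
                    label_events(t[2], labels))

        checked = 0
        for shape in all_shapes(leaves):
            for sp_bits in itertools.product("AB", repeat=4):
                species = dict(zip(leaves, sp_bits))
                for ev_bits in itertools.product("DS", repeat=3):
                    t = label_events(shape, list(ev_bits))
                    table = gene_table(*[(g, species[g]) for g in leaves])
                    tree = parse_gene_tree(tuple_to_newick(t) + ";", table)
                    got = classes_of(classify_homolog_pairs(tree))
                    assert got == oracle_classify(t, species)
                    checked += 1
        assert checked == 15 * 16 * 8

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_random_trees_match_oracle(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(300):
            t = random_tuple_tree(n_leaves, rng)
            species = {f"g{i}": ("A" if rng.random() < 0.5 else "B")
                       for i in range(n_leaves)}
            table = gene_table(*[(g, s) for g, s in species.items()])
            tree = parse_gene_tree(tuple_to_newick(t) + ";", table)
            got = classes_of(classify_homolog_pairs(tree))
            assert got == oracle_classify(t, species)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            t = random_tuple_tree(5, rng)
            species = {f"g{i}": ("A" if i % 2 else "B") for i in range(5)}
            table = gene_table(*[(g, s) for g, s in species.items()])

            def rotate(x):
                if isinstance(x, str):
                    return x
                return (x[0], rotate(x[2]), rotate(x[1]))

            a = classes_of(classify_homolog_pairs(
                parse_gene_tree(tuple_to_newick(t) + ";", table)))
            b = classes_of(classify_homolog_pairs(
                parse_gene_tree(tuple_to_newick(rotate(t)) + ";", table)))
            assert a == b


class TestSpeciesSeparationInvariant:
    """Same-species pairs can never be called orthologs and vice versa."""

    def test_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            t = random_tuple_tree(n, rng)
            species = {f"g{i}": ("A" if rng.random() < 0.5 else "B")
                       for i in range(n)}
            table = gene_table(*[(g, s) for g, s in species.items()])
            tree = parse_gene_tree(tuple_to_newick(t) + ";", table)
            for p in classify_homolog_pairs(tree):
                same = species[p.gene_a] == species[p.gene_b]
                if same:
                    assert p.cls in (INPARALOG, WS_OUTPARALOG)
                else:
                    assert p.cls in (ORTHOLOG_1TO1, ORTHOLOG_MANY, BS_OUTPARALOG)

    def test_unlabeled_tree_is_hard_error(self, two_species_genes):
        t = parse_gene_tree("(H1,M1);", two_species_genes)
        with pytest.raises(TreeError, match="unlabeled"):
            classify_homolog_pairs(t)
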