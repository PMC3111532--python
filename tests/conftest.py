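"""Shared fixtures: tiny hand-built ontologies, trees and tables."""

import io
import textwrap

import pytest

from orthoconj.homology import GeneRecord
from orthoconj.ontology import load_obo


def obo_from_terms(stanzas: str) -> str:
    return "format-version: 1.2\n\n" + textwrap.dedent(stanzas)


@pytest.fixture
def chain_obo():
    """root <- mid <- leaf."""
    return obo_from_terms("""\
        [Term]
        id: GO:0000001
        name: root
        namespace: biological_process

        [Term]
        id: GO:0000002
        name: mid
        namespace: biological_process
        is_a: GO:0000001

        [Term]
        id: GO:0000003
        name: leaf
        namespace: biological_process
        is_a: GO:0000002
        """)


@pytest.fixture
def diamond_obo():
    """leaf with two parents (one via part_of) that share the root."""
    return obo_from_terms("""\
        [Term]
        id: GO:0000001
        name: root
        namespace: biological_process

        [Term]
        id: GO:0000002
        name: p1
        namespace: biological_process
        is_a: GO:0000001

        [Term]
        id: GO:0000003
        name: p2
        namespace: biological_process
        relationship: part_of GO:0000001

        [Term]
        id: GO:0000004
        name: leaf
        namespace: biological_process
        is_a: GO:0000002
        is_a: GO:0000003

        [Term]
        id: GO:0000005
        name: gone
        namespace: biological_process
        is_a: GO:0000001
        is_obsolete: true
        """)


@pytest.fixture
def diamond_dag(diamond_obo):
    return load_obo(io.StringIO(diamond_obo), namespace="biological_process")


def gene_table(*entries) -> dict:
    """entries: (gene_id, species[, chromosome]) tuples."""
    out = {}
    for e in entries:
        gid, sp = e[0], e[1]
        chrom = e[2] if len(e) > 2 else "chr1"
        out[gid] = GeneRecord(gid, sp, chrom)
    return out


@pytest.fixture
def two_species_genes():
    return gene_table(("H1", "A"), ("H2", "A"), ("H3", "A"), ("H4", "A"),
                      ("M1", "B"), ("M2", "B"))


@pytest.fixture
def one_to_many_tree():
    """One pre-split duplication and two nested post-split human duplications.

    M1 is co-orthologous to H1-H3; H1-H3 are mutual inparalogs; M1/M2 are
    within-species outparalogs; M1/H4 between-species outparalogs.
    """
    return ("((((H1:1,H2:1):1[&&NHX:D=Y],H3:2):1[&&NHX:D=Y],M1:3):1[&&NHX:D=N],"
            "(H4:3,M2:3):1[&&NHX:D=N]):0[&&NHX:D=Y];")


@pytest.fixture
def two_pairs_tree():
    """Pre-split duplication followed by two speciations: two 1:1 pairs."""
    return "((H1:2,M1:2):1[&&NHX:D=N],(H2:2,M2:2):1[&&NHX:D=N]):0[&&NHX:D=Y];"
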