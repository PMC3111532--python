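"""End-to-end orchestration: files in, pair table and reports out.

Stages run in a fixed order: annotate -> classify -> sequence similarity ->
expression -> functional similarity -> curves / family analysis.  Every run
writes a manifest (seed, input checksums, per-stage counts) and plain TSV
tables referencing it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (assemble_pair_table, bin_curve,
                       chromosome_split_curves, compare_classes,
                       trend_correlation)
from .expression import (expression_similarity, map_probes_to_genes,
                         normalize_two_step, read_expression_tsv)
from .family import run_family_analysis, split_pair_table_by_family
from .funcsim import jaccard, maryland_bridge
from .homology import (ORTHOLOG_1TO1, PARALOG_CLASSES, read_gene_table,
                       read_gene_trees, label_events_species_overlap,
                       classify_homolog_pairs, treat_apparent_orthologs)
from .ontology import load_obo, propagate_annotations, read_gaf
from .seqsim import estimate_divergence, global_align, percent_identity

log = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function")


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def classify_dataset(trees_path, genes_path, relabel: bool = False,
                     merge_apparent: bool = True):
    """Parse trees, label events, classify and post-process all pairs."""
    gene_table = read_gene_table(genes_path)
    trees = read_gene_trees(trees_path, gene_table)
    pairs = []
    for i, tree in enumerate(trees):
        label_events_species_overlap(tree, force=relabel)
        pairs.extend(classify_homolog_pairs(tree, family_id=f"F{i:04d}"))
    pairs = treat_apparent_orthologs(pairs, merge=merge_apparent)
    return pairs, gene_table


def sequence_similarity_table(pairs, proteins: dict[str, str],
                              cds: dict[str, str] | None = None) -> pd.DataFrame:
    """Identity (and, when CDS given, dN/dS and dS) for every pair."""
    rows = []
    for p in pairs:
        if p.gene_a not in proteins or p.gene_b not in proteins:
            continue
        aln = global_align(proteins[p.gene_a], proteins[p.gene_b])
        row = {"gene_a": p.gene_a, "gene_b": p.gene_b,
               "identity": percent_identity(aln)}
        if cds is not None and p.gene_a in cds and p.gene_b in cds:
            est = estimate_divergence(cds[p.gene_a], cds[p.gene_b], aln)
            row |= {"dn_ds": est.dn_ds,
                    "ds": est.dS if est.ds_reliable else np.nan}
        rows.append(row)
    return pd.DataFrame(rows)


def functional_similarity_table(pairs, annotation_sets_by_ns) -> pd.DataFrame:
    """Maryland bridge fs (plus Jaccard) per pair and namespace."""
    rows = []
    for namespace, annotation_sets in annotation_sets_by_ns.items():
        for p in pairs:
            sa = annotation_sets.get(p.gene_a)
            sb = annotation_sets.get(p.gene_b)
            if sa is None or sb is None:
                continue
            score = maryland_bridge(sa.terms, sb.terms)
            rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b,
                         "namespace": namespace, "fs": score.value,
                         "jaccard": jaccard(sa.terms, sb.terms),
                         "size_a": score.size_p, "size_b": score.size_q,
                         "intersection": score.intersection})
    return pd.DataFrame(rows)


def functional_similarity_table_biased(
        pairs, records, dag, *, drop_tas: bool = False,
        shared_terms: bool = False, depth_truncate: bool = False,
        family_of: dict[str, str] | None = None,
        pub_mode: str | None = None, evidence_same_code: bool = False,
        per_protein_codes: bool = False, depth_path: str = "shortest"
) -> tuple[pd.DataFrame, list]:
    """fs per pair under the requested bias filters.

    Global filters (drop_tas, shared_terms, depth_truncate) transform the
    annotation corpus once; pair-level filters (pub_mode in
    {'separate', 'same_only'}, evidence_same_code) re-filter the two
    proteins' records for every comparison before propagation.  Returns
    the fs table and the list of FilterReports produced.
    """
    from .biases import (exclude_same_publication_pairs,
                         filter_shared_species_terms, pair_term_sets,
                         restrict_evidence, truncate_family_depth)
    from .funcsim import maryland_bridge
    from .ontology import propagate_annotations, term_depths

    reports = []
    records = [r for r in records if r.term_id in dag]
    if drop_tas:
        before = len(records)
        records = restrict_evidence(records, mode="drop_TAS")
        from .biases import FilterReport
        reports.append(FilterReport("drop_TAS", before, len(records)))
    by_protein: dict[str, list] = {}
    for r in records:
        by_protein.setdefault(r.protein_id, []).append(r)

    pairwise = pub_mode is not None or evidence_same_code

    sets = propagate_annotations(records, dag)
    if shared_terms:
        species_of = {r.protein_id: r.species for r in records}
        sets, rep = filter_shared_species_terms(sets, species_of)
        reports.append(rep)
    if depth_truncate:
        if family_of is None:
            raise ValueError("depth truncation needs a protein -> family map")
        depths = term_depths(dag, path=depth_path)
        by_family: dict[str, dict] = {}
        for pid, aset in sets.items():
            by_family.setdefault(family_of.get(pid, ""), {})[pid] = aset
        sets = {}
        for fam_sets in by_family.values():
            truncated, rep = truncate_family_depth(fam_sets, depths)
            reports.append(rep)
            sets.update(truncated)

    rows = []
    for p in pairs:
        if pairwise:
            rp = by_protein.get(p.gene_a, [])
            rq = by_protein.get(p.gene_b, [])
            if pub_mode is not None:
                rp, rq = exclude_same_publication_pairs(rp, rq, mode=pub_mode)
            if evidence_same_code:
                rp, rq = restrict_evidence(rp, rq, mode="same_code",
                                           per_protein=per_protein_codes)
            terms_p, terms_q = pair_term_sets(rp, rq, dag)
            # global filters still apply on top of the pairwise selection
            if p.gene_a in sets:
                terms_p = terms_p & sets[p.gene_a].terms
            elif shared_terms or depth_truncate:
                terms_p = frozenset()
            if p.gene_b in sets:
                terms_q = terms_q & sets[p.gene_b].terms
            elif shared_terms or depth_truncate:
                terms_q = frozenset()
        else:
            terms_p = sets[p.gene_a].terms if p.gene_a in sets else frozenset()
            terms_q = sets[p.gene_b].terms if p.gene_b in sets else frozenset()
        if not terms_p or not terms_q:
            continue
        score = maryland_bridge(terms_p, terms_q)
        rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b,
                     "namespace": dag.namespace, "fs": score.value})
    return pd.DataFrame(rows), reports


def expression_similarity_table(pairs, gene_matrix: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for p in pairs:
        if p.gene_a in gene_matrix.index and p.gene_b in gene_matrix.index:
            corr = expression_similarity(gene_matrix.loc[p.gene_a],
                                         gene_matrix.loc[p.gene_b])
            rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b,
                         "expr_corr": corr})
    return pd.DataFrame(rows)


def analyze_dataset(dataset_dir, namespaces=NAMESPACES, relabel: bool = False,
                    merge_apparent: bool = True, with_expression: bool = True,
                    with_divergence: bool = False, family_reps: int = 100,
                    seed: int = 0) -> dict:
    """Run the full analysis over a dataset directory.

    Expects the file layout written by :func:`orthoconj.simulate.generate_dataset`
    (ontology.obo, genes.tsv, trees.nwk, proteins.fa, cds.fa,
    annotations.tsv, expression.tsv, probes.fa, transcripts.fa).  Returns a
    dict with the pair table, per-class curves, trend and class tests, the
    chromosome split, and the family-based table.
    """
    d = Path(dataset_dir)
    pairs, gene_table = classify_dataset(d / "trees.nwk", d / "genes.tsv",
                                         relabel=relabel,
                                         merge_apparent=merge_apparent)
    records = read_gaf(d / "annotations.tsv")
    annotation_sets = {}
    for namespace in namespaces:
        dag = load_obo(str(d / "ontology.obo"), namespace=namespace)
        annotation_sets[namespace] = propagate_annotations(records, dag)
    proteins = _read_fasta(d / "proteins.fa")
    cds = _read_fasta(d / "cds.fa") if with_divergence else None
    seq_df = sequence_similarity_table(pairs, proteins, cds)
    fs_df = functional_similarity_table(pairs, annotation_sets)

    expr_df = None
    if with_expression and (d / "expression.tsv").exists():
        pmap = map_probes_to_genes(d / "probes.fa", d / "transcripts.fa")
        matrix = read_expression_tsv(d / "expression.tsv")
        em = normalize_two_step(matrix, probeset_map=pmap)
        expr_df = expression_similarity_table(pairs, em.genes)

    table = assemble_pair_table(pairs, seq_df=seq_df, fs_df=fs_df,
                                expr_df=expr_df, gene_table=gene_table)

    results = {"pair_table": table, "pairs": pairs, "gene_table": gene_table,
               "annotation_sets": annotation_sets}
    curves = {}
    tests = {}
    for ns, col in (("biological_process", "fs_BP"),
                    ("molecular_function", "fs_MF")):
        if ns not in namespaces:
            continue
        curves[f"ortholog_{col}"] = bin_curve(table, "identity", col,
                                              ORTHOLOG_1TO1)
        curves[f"paralog_{col}"] = bin_curve(table, "identity", col,
                                             list(PARALOG_CLASSES))
        try:
            tests[f"trend_ortholog_{col}"] = trend_correlation(
                table, ORTHOLOG_1TO1, "identity", col)
            tests[f"trend_paralog_{col}"] = trend_correlation(
                table, list(PARALOG_CLASSES), "identity", col)
            tests[f"wilcoxon_paralog_vs_ortholog_{col}"] = compare_classes(
                table, list(PARALOG_CLASSES), ORTHOLOG_1TO1, col,
                identity_threshold=0.7)
        except ValueError as exc:
            log.warning("skipping test for %s: %s", col, exc)
        same, diff, n_excl = chromosome_split_curves(table, y_variable=col)
        curves[f"same_chromosome_{col}"] = same
        curves[f"different_chromosome_{col}"] = diff
    results["curves"] = curves
    results["tests"] = tests

    families = split_pair_table_by_family(table)
    results["family_tables"] = {
        ns: run_family_analysis(families, ns, n_reps=family_reps, seed=seed)
        for ns in namespaces
    }
    return results


def write_results(results: dict, outdir, manifest: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    mid = manifest["manifest_id"]

    def dump(df: pd.DataFrame, name: str):
        with open(outdir / name, "w") as fh:
            fh.write(f"# manifest: {mid}\n")
            df.to_csv(fh, sep="\t", index=False)

    dump(results["pair_table"].drop(columns=["species_a", "species_b"],
                                    errors="ignore"), "pair_table.tsv")
    for name, curve in results["curves"].items():
        dump(curve.table, f"curve_{name}.tsv")
    test_rows = []
    for name, value in results["tests"].items():
        test_rows.append({"test": name, "statistic": value[0], "extra": value[1]})
    dump(pd.DataFrame(test_rows), "tests.tsv")
    for ns, fam in results["family_tables"].items():
        dump(fam.mean.reset_index(names="row"), f"family_mean_{ns}.tsv")
        dump(fam.se.reset_index(names="row"), f"family_se_{ns}.tsv")
        dump(fam.percentages.reset_index(names="row"),
             f"family_percent_{ns}.tsv")


def run_pipeline(dataset_dir, outdir, seed: int = 0, family_reps: int = 100,
                 with_divergence: bool = False) -> Path:
    """Execute the full pipeline and write all tables plus a manifest."""
    d = Path(dataset_dir)
    inputs = sorted(p for p in d.iterdir() if p.is_file())
    checksums = {p.name: _sha256(p) for p in inputs}
    results = analyze_dataset(d, seed=seed, family_reps=family_reps,
                              with_divergence=with_divergence)
    manifest = {
        "manifest_id": hashlib.sha256(
            json.dumps(checksums, sort_keys=True).encode()
        ).hexdigest()[:12],
        "tool_version": __version__,
        "seed": seed,
        "inputs": checksums,
        "counts": {
            "pairs": int(len(results["pair_table"])),
            "pairs_by_class": {
                k: int(v) for k, v in
                results["pair_table"].groupby("cls").size().items()
            },
        },
    }
    write_results(results, outdir, manifest)
    return Path(outdir)
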