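"""The synthetic-data generator: determinism, consistency, closed forms."""

import hashlib
import io
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from orthoconj.expression import (map_probes_to_genes, normalize_two_step,
                                  read_expression_tsv)
from orthoconj.ontology import load_obo
from orthoconj.pipeline import classify_dataset, expression_similarity_table
from orthoconj.seqsim import alignment_identity
from orthoconj.simulate import (SimulationConfig, generate_dataset,
                                generate_obo, generate_ontology,
                                simulate_family)


def dir_hash(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(path).iterdir()):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


@pytest.fixture(scope="module")
def small_dataset(tmp_path_factory):
    cfg = SimulationConfig(seed=5, n_families=40)
    out = tmp_path_factory.mktemp("ds") / "d"
    return cfg, generate_dataset(cfg, out)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tissues=2)
        with pytest.raises(ValueError):
            SimulationConfig(annotation_sparsity=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(loss_rate=-0.1)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_families=7, delta=0.25)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestOntologyGeneration:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_output_always_loads(self, seed):
        rng = np.random.default_rng(seed)
        text = "format-version: 1.2\n\n" + generate_ontology(
            60, 4, 6, rng, namespace="biological_process", prefix="GO:X")
        dag = load_obo(io.StringIO(text), namespace="biological_process")
        assert len(dag.terms) == 60  # the obsolete extra is dropped

    def test_minimal_ontology(self):
        rng = np.random.default_rng(0)
        text = "format-version: 1.2\n\n" + generate_ontology(
            3, 2, 3, rng, namespace="biological_process", prefix="GO:X")
        dag = load_obo(io.StringIO(text), namespace="biological_process")
        assert len(dag.terms) == 3
        assert all(dag.root in dag.ancestors(t) | {t} for t in dag.terms)

    def test_same_seed_same_bytes(self):
        cfg = SimulationConfig(seed=3)
        a = generate_obo(cfg, np.random.default_rng(3))
        b = generate_obo(cfg, np.random.default_rng(3))
        assert a == b


class TestFamilyTrees:
    def test_zero_duplication_rate_gives_pure_ortholog_pairs(self, tmp_path):
        cfg = SimulationConfig(seed=2, n_families=12, dup_rate=0.0)
        ds = generate_dataset(cfg, tmp_path / "d")
        assert set(ds.truth_pairs.true_class) == {"ortholog_1to1"}
        assert len(ds.truth_pairs) == 12

    def test_prespeciation_duplication_produces_outparalogs(self):
        cfg = SimulationConfig(seed=0, t_speciation=1.0, t_total=1.2,
                               dup_rate=2.0)
        rng = np.random.default_rng(1)
        found = False
        for i in range(20):
            root = simulate_family(cfg, rng, f"F{i}")
            from orthoconj.simulate import true_pair_classes
            classes = {r["true_class"]
                       for r in true_pair_classes(root, cfg, f"F{i}")}
            if "between_species_outparalog" in classes:
                found = True
                assert ("within_species_outparalog" in classes
                        or "between_species_outparalog" in classes)
        assert found

    def test_inparalog_fraction_grows_with_duplication_rate(self, tmp_path):
        fracs = []
        for rate in (0.1, 0.8):
            cfg = SimulationConfig(seed=4, n_families=150, dup_rate=rate)
            ds = generate_dataset(cfg, tmp_path / f"r{rate}")
            counts = ds.truth_pairs.true_class.value_counts()
            fracs.append(counts.get("inparalog", 0) / len(ds.truth_pairs))
        assert fracs[1] > fracs[0]

    def test_ground_truth_matches_classifier(self, small_dataset):
        _, ds = small_dataset
        pairs, _ = classify_dataset(ds.trees, ds.genes, merge_apparent=False)
        pred = {(p.gene_a, p.gene_b): p.cls for p in pairs}
        for r in ds.truth_pairs.itertuples():
            assert pred[(r.gene_a, r.gene_b)] == r.true_class


class TestSequences:
    def test_zero_rates_give_identical_sequences(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_families=5, aa_rate=0.0, syn_rate=0.0)
        ds = generate_dataset(cfg, tmp_path / "d")
        from Bio import SeqIO
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(ds.proteins), "fasta")}
        for r in ds.truth_pairs.itertuples():
            assert seqs[r.gene_a] == seqs[r.gene_b]

    def test_ortholog_identity_matches_closed_form(self, tmp_path):
        """Mean identity of same-age orthologs equals the 20-state
        jump-process expectation within 3 Monte-Carlo SEs."""
        cfg = SimulationConfig(seed=6, n_families=150, rate_sigma=0.0,
                               dup_rate=0.0)
        ds = generate_dataset(cfg, tmp_path / "d")
        from Bio import SeqIO
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(ds.proteins), "fasta")}
        idents = [alignment_identity(seqs[r.gene_a], seqs[r.gene_b])
                  for r in ds.truth_pairs.itertuples()]
        tau = 2.0 * (cfg.t_total - cfg.t_speciation)
        expected = 1 / 20 + (19 / 20) * math.exp(-(20 / 19) * cfg.aa_rate * tau)
        se = np.std(idents, ddof=1) / np.sqrt(len(idents))
        assert abs(np.mean(idents) - expected) < 3 * se + 1e-9


class TestAnnotations:
    def test_frozen_annotations_give_full_similarity(self, tmp_path):
        cfg = SimulationConfig(seed=3, n_families=10, gain_rate=0.0,
                               loss_rate=0.0, delta=0.0,
                               annotation_sparsity=1.0)
        ds = generate_dataset(cfg, tmp_path / "d")
        ann = pd.read_csv(ds.annotations, sep="\t",
                          names=["protein_id", "species", "term_id",
                                 "evidence_code", "pubmed_ids"], comment="#")
        bp = ann[ann.term_id.str.startswith("GO:BP")]
        by_protein = bp.groupby("protein_id").term_id.apply(frozenset)
        for r in ds.truth_pairs.itertuples():
            assert by_protein[r.gene_a] == by_protein[r.gene_b]

    def test_fs_decreases_with_divergence_time(self, small_dataset):
        from orthoconj.pipeline import analyze_dataset
        _, ds = small_dataset
        res = analyze_dataset(ds.root, with_expression=False, family_reps=1)
        t = res["pair_table"].merge(
            ds.truth_pairs, on=["gene_a", "gene_b"]).dropna(subset=["fs_BP"])
        from scipy.stats import spearmanr
        rho, p = spearmanr(t.divergence_time, t.fs_BP)
        assert rho < 0 and p < 0.05


class TestExpression:
    def test_zero_variance_gives_perfect_correlation(self, tmp_path):
        cfg = SimulationConfig(seed=8, n_families=10, expr_sigma2=0.0,
                               expr_delta=0.0, probe_noise_sd=0.0,
                               ambiguous_probeset_frac=0.0)
        ds = generate_dataset(cfg, tmp_path / "d")
        pmap = map_probes_to_genes(ds.probes, ds.transcripts)
        em = normalize_two_step(read_expression_tsv(ds.expression),
                                probeset_map=pmap)
        pairs, _ = classify_dataset(ds.trees, ds.genes)
        expr = expression_similarity_table(pairs, em.genes)
        assert np.allclose(expr.expr_corr, 1.0)

    def test_correlation_decreases_with_divergence_time(self, small_dataset):
        _, ds = small_dataset
        pmap = map_probes_to_genes(ds.probes, ds.transcripts)
        em = normalize_two_step(read_expression_tsv(ds.expression),
                                probeset_map=pmap)
        pairs, _ = classify_dataset(ds.trees, ds.genes)
        expr = expression_similarity_table(pairs, em.genes)
        t = expr.merge(ds.truth_pairs, on=["gene_a", "gene_b"])
        from scipy.stats import spearmanr
        rho, p = spearmanr(t.divergence_time, t.expr_corr)
        assert rho < 0 and p < 0.05

    def test_ambiguous_probesets_rejected(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_families=15,
                               ambiguous_probeset_frac=0.5)
        ds = generate_dataset(cfg, tmp_path / "d")
        pmap = map_probes_to_genes(ds.probes, ds.transcripts)
        assert any("multiple genes" in reason
                   for reason in pmap.rejected.values())


class TestDeterminism:
    def test_byte_identical_datasets_under_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_families=15)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        assert dir_hash(tmp_path / "a") == dir_hash(tmp_path / "b")

    def test_different_seed_changes_output(self, tmp_path):
        generate_dataset(SimulationConfig(seed=1, n_families=5), tmp_path / "a")
        generate_dataset(SimulationConfig(seed=2, n_families=5), tmp_path / "b")
        assert dir_hash(tmp_path / "a") != dir_hash(tmp_path / "b")
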