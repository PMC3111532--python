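"""Synthetic two-species comparative-genomics datasets.

The generator emulates the statistical structure of a human/mouse-style
study: gene families arising from a birth process of duplications around a
single speciation event, codon sequences diverging under independent
synonymous/nonsynonymous substitution, sparse ontology annotations evolving
by term gain and loss, and a tissue expression panel drifting by Brownian
motion.  Two plantable effects drive the study's qualitative findings:

* a *species context shift* ``delta`` — one shared pulse of annotation
  (and expression) divergence per species at the speciation boundary, so
  cross-species pairs diverge beyond what their age alone explains while
  same-species pairs, which share the pulse, do not;
* an *interchromosomal multiplier* — gene copies relocated to a new
  chromosome at duplication accrue annotation divergence at a multiplied
  rate, separating same- from different-chromosome paralogs.

All randomness flows from a single seed; the emitted file set is
byte-identical across runs with an equal configuration.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .ontology import load_obo, ALLOWED_EVIDENCE_CODES
from .seqsim import AMINO_ACIDS, _STANDARD_TABLE

SPECIES = ("A", "B")

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_SENSE_CODONS = sorted(_STANDARD_TABLE.forward_table)


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study's default conditions."""

    seed: int = 0
    n_families: int = 500
    # tree process (times in arbitrary units; speciation at t_speciation,
    # leaves sampled at t_total)
    t_speciation: float = 1.0
    t_total: float = 2.0
    dup_rate: float = 0.25          # duplications per lineage per unit time
    p_relocate: float = 0.3         # P(new copy moves to another chromosome)
    n_chromosomes: int = 20
    max_family_leaves: int = 24
    # sequences
    n_codons: int = 120
    aa_rate: float = 0.06           # amino-acid substitutions per codon per time
    syn_rate: float = 0.12          # synonymous substitutions per codon per time
    rate_sigma: float = 0.7         # lognormal sd of per-family rate multiplier
    # annotations
    initial_terms: int = 8          # ancestral leaf-term count per namespace
    gain_rate: float = 1.5          # term gains per unit time
    loss_rate: float = 0.25         # per-term loss rate per unit time
    delta: float = 1.0              # species context shift (time-equivalent)
    interchrom_multiplier: float = 3.0
    annotation_sparsity: float = 0.6
    evidence_share_p: float = 0.7
    pub_share_p: float = 0.5
    pub_extra_p: float = 0.15       # annotation carries shared AND own PubMed id
    # expression
    n_tissues: int = 25
    expr_sigma2: float = 0.3        # Brownian variance per unit time
    expr_delta: float = 1.0         # context shift for expression
    probes_per_set: int = 16
    probe_length: int = 25
    utr_length: int = 150           # fast-evolving 3' region probes target
    utr_rate: float = 0.5           # substitutions per UTR site per unit time
    ambiguous_probeset_frac: float = 0.05
    multi_probeset_frac: float = 0.1
    duplicate_tissue_frac: float = 0.1
    probe_noise_sd: float = 0.05    # per-probeset measurement noise (log scale)
    # ontology
    ontology_terms: int = 150       # per namespace
    ontology_max_children: int = 4
    ontology_depth: int = 8
    ontology_diamond_frac: float = 0.15

    def __post_init__(self):
        if self.n_tissues < 3:
            raise ValueError("n_tissues must be >= 3")
        for name in ("dup_rate", "aa_rate", "syn_rate", "gain_rate", "loss_rate",
                     "delta", "expr_sigma2", "expr_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_relocate", "annotation_sparsity", "evidence_share_p",
                     "pub_share_p", "pub_extra_p", "ambiguous_probeset_frac",
                     "multi_probeset_frac", "duplicate_tissue_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass(eq=False)
class SimNode:
    """Node of a simulated family tree; ``time`` is the node's event age."""

    time: float
    event: str | None = None        # speciation / duplication / None (leaf)
    species: str | None = None      # set for leaves and post-speciation lineages
    chromosome: str = "chr1"
    relocated: bool = False         # lineage descends from a relocation
    children: list = field(default_factory=list)
    name: str | None = None         # leaf gene id


@dataclass
class SyntheticDataset:
    """Paths of the emitted file set plus the in-memory ground truth."""

    root: Path
    obo: Path
    genes: Path
    trees: Path
    proteins: Path
    cds: Path
    annotations: Path
    expression: Path
    probes: Path
    transcripts: Path
    ground_truth: Path
    config: Path
    truth_pairs: "pd.DataFrame" = None  # noqa: F821 - assigned by generate_dataset


# --- ontology --------------------------------------------------------------

def generate_ontology(n_terms: int, max_children: int, depth: int,
                      rng: np.random.Generator,
                      namespace: str = "biological_process",
                      prefix: str = "GO:BP", diamond_frac: float = 0.15) -> str:
    """OBO stanzas for one namespace: a rooted random DAG with diamonds.

    Terms attach under a uniformly chosen existing term with spare child
    capacity and depth < ``depth``; a fraction of non-root terms then gain
    a second (``part_of``) parent, creating diamond motifs.
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    ids = [f"{prefix}:{i:07d}" for i in range(n_terms)]
    parents: dict[str, list[tuple[str, str]]] = {ids[0]: []}
    depths = {ids[0]: 0}
    n_children = {ids[0]: 0}
    for term in ids[1:]:
        candidates = [t for t in parents
                      if depths[t] < depth and n_children[t] < max_children]
        if not candidates:
            candidates = [t for t in parents if depths[t] < depth] or [ids[0]]
        parent = candidates[rng.integers(len(candidates))]
        parents[term] = [("is_a", parent)]
        depths[term] = depths[parent] + 1
        n_children[term] = 0
        n_children[parent] = n_children.get(parent, 0) + 1
    # diamonds: second parents at a strictly shallower depth (keeps acyclicity)
    for term in ids[1:]:
        if rng.random() < diamond_frac:
            shallower = [t for t in parents
                         if depths[t] < depths[term] and t != parents[term][0][1]]
            if shallower:
                extra = shallower[rng.integers(len(shallower))]
                rel = "part_of" if rng.random() < 0.5 else "is_a"
                parents[term].append((rel, extra))
    lines = []
    for i, term in enumerate(ids):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic {namespace} term {i}")
        lines.append(f"namespace: {namespace}")
        for rel, parent in parents[term]:
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    # one obsolete term, exercising the loader's filter
    lines += ["[Term]", f"id: {prefix}:9999999", "name: obsolete synthetic term",
              f"namespace: {namespace}", "is_obsolete: true", ""]
    return "\n".join(lines)


def generate_obo(config: SimulationConfig, rng: np.random.Generator) -> str:
    header = "format-version: 1.2\nontology: synthetic\n\n"
    bp = generate_ontology(config.ontology_terms, config.ontology_max_children,
                           config.ontology_depth, rng,
                           namespace="biological_process", prefix="GO:BP",
                           diamond_frac=config.ontology_diamond_frac)
    mf = generate_ontology(config.ontology_terms, config.ontology_max_children,
                           config.ontology_depth, rng,
                           namespace="molecular_function", prefix="GO:MF",
                           diamond_frac=config.ontology_diamond_frac)
    return header + bp + "\n" + mf


# --- gene-family trees -----------------------------------------------------

def simulate_family(config: SimulationConfig, rng: np.random.Generator,
                    family_id: str) -> SimNode:
    """Birth process of duplications around one speciation event.

    Every lineage alive at ``t_speciation`` splits into one copy per
    species; duplications occur at rate ``dup_rate`` per lineage both
    before and after the split.  Oversized families are redrawn.
    """
    for _attempt in range(100):
        counter = {s: 0 for s in SPECIES}

        def evolve(start: float, species: str | None, chromosome: str,
                   relocated: bool) -> SimNode:
            wait = rng.exponential(1.0 / config.dup_rate) if config.dup_rate > 0 else math.inf
            t_next = start + wait
            if species is None and t_next >= config.t_speciation:
                node = SimNode(time=config.t_speciation, event="speciation",
                               chromosome=chromosome, relocated=relocated)
                for sp in SPECIES:
                    node.children.append(evolve(config.t_speciation, sp,
                                                chromosome, relocated))
                return node
            if t_next < config.t_total:
                node = SimNode(time=t_next, event="duplication", species=species,
                               chromosome=chromosome, relocated=relocated)
                node.children.append(evolve(t_next, species, chromosome, relocated))
                if rng.random() < config.p_relocate:
                    new_chrom = f"chr{rng.integers(1, config.n_chromosomes + 1)}"
                    node.children.append(evolve(t_next, species, new_chrom, True))
                else:
                    node.children.append(evolve(t_next, species, chromosome,
                                                relocated))
                return node
            counter[species] += 1
            return SimNode(time=config.t_total, species=species,
                           chromosome=chromosome, relocated=relocated,
                           name=f"{family_id}_{species}{counter[species]}")

        chromosome = f"chr{rng.integers(1, config.n_chromosomes + 1)}"
        root = evolve(0.0, None, chromosome, False)
        if sum(counter.values()) <= config.max_family_leaves:
            return root
    raise RuntimeError("family simulation kept exceeding max_family_leaves")


def iter_leaves(node: SimNode):
    if not node.children:
        yield node
    for child in node.children:
        yield from iter_leaves(child)


def to_newick(node: SimNode, parent_time: float = 0.0) -> str:
    bl = node.time - parent_time
    if not node.children:
        return f"{node.name}:{bl:.6f}"
    inner = ",".join(to_newick(c, node.time) for c in node.children)
    tag = "Y" if node.event == "duplication" else "N"
    return f"({inner}):{bl:.6f}[&&NHX:D={tag}]"


def family_newick(root: SimNode) -> str:
    return to_newick(root) + ";"


def true_pair_classes(root: SimNode, config: SimulationConfig,
                      family_id: str) -> list[dict]:
    """Ground-truth class and divergence time for every leaf pair.

    Classified directly from the generating process (LCA event, node age
    relative to the speciation time, species identity) — independent of
    the tree-parsing/classification code path.
    """
    leaves = list(iter_leaves(root))
    paths: dict[str, list[SimNode]] = {}

    def walk(node, path):
        path = path + [node]
        if not node.children:
            paths[node.name] = path
        for c in node.children:
            walk(c, path)

    walk(root, [])
    rows = []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            pa, pb = paths[a.name], paths[b.name]
            lca = None
            for x, y in zip(pa, pb):
                if x is y:
                    lca = x
                else:
                    break
            same_species = a.species == b.species
            below = {x for p in (pa, pb) for x in p[p.index(lca) + 1:]}
            dup_below = any(n.event == "duplication" for n in below
                            if n.children)
            if lca.event == "speciation":
                cls = "ortholog_1toMany_or_Many" if dup_below else "ortholog_1to1"
            elif same_species:
                cls = ("inparalog" if lca.time > config.t_speciation
                       else "within_species_outparalog")
            else:
                cls = "between_species_outparalog"
            rows.append({
                "gene_a": min(a.name, b.name), "gene_b": max(a.name, b.name),
                "true_class": cls, "family_id": family_id,
                "divergence_time": 2.0 * (config.t_total - lca.time),
                "same_chromosome": (a.chromosome == b.chromosome
                                    if same_species else None),
            })
    return rows


# --- sequences -------------------------------------------------------------

def _random_codon_sequence(n_codons: int, rng) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def _mutate_codon(codon: str, n_aa_jumps: int, n_syn_jumps: int, rng) -> str:
    aa = _STANDARD_TABLE.forward_table[codon]
    for _ in range(int(n_aa_jumps)):
        others = [x for x in AMINO_ACIDS if x != aa]
        aa = others[rng.integers(len(others))]
        codons = _CODONS_BY_AA[aa]
        codon = codons[rng.integers(len(codons))]
    for _ in range(int(n_syn_jumps)):
        codons = _CODONS_BY_AA[aa]
        codon = codons[rng.integers(len(codons))]
    return codon


def evolve_sequences(root: SimNode, config: SimulationConfig,
                     rng: np.random.Generator,
                     rate_multiplier: float = 1.0) -> dict[str, str]:
    """Evolve a codon sequence down the family tree.

    Per codon and branch, amino-acid replacements are Poisson with rate
    ``aa_rate * multiplier`` (each jump uniform over the 19 other amino
    acids, codon uniform within the new amino acid) and synonymous codon
    changes Poisson with ``syn_rate * multiplier``.  Returns leaf CDS
    strings; proteins are their translations.
    """
    ancestral = _random_codon_sequence(config.n_codons, rng)
    out: dict[str, str] = {}

    def walk(node: SimNode, seq: list[str], parent_time: float):
        t = (node.time - parent_time) * rate_multiplier
        if t > 0:
            seq = list(seq)
            n_aa = rng.poisson(config.aa_rate * t, size=len(seq))
            n_syn = rng.poisson(config.syn_rate * t, size=len(seq))
            for i in np.nonzero(n_aa + n_syn)[0]:
                seq[i] = _mutate_codon(seq[i], n_aa[i], n_syn[i], rng)
        if not node.children:
            out[node.name] = "".join(seq)
        for c in node.children:
            walk(c, seq, node.time)

    walk(root, ancestral, 0.0)
    return out


def evolve_utrs(root: SimNode, config: SimulationConfig,
                rng: np.random.Generator) -> dict[str, str]:
    """Evolve an untranslated 3' region down the tree (per-site JC-style).

    Microarray probes target this fast-evolving region, so probesets are
    gene-specific except between very young duplicates — mirroring real
    3'-biased array designs.
    """
    bases = "ACGT"
    ancestral = "".join(bases[i] for i in
                        rng.integers(0, 4, size=config.utr_length))
    out: dict[str, str] = {}

    def walk(node: SimNode, seq: str, parent_time: float):
        t = node.time - parent_time
        if t > 0 and config.utr_rate > 0:
            arr = list(seq)
            n_sub = rng.poisson(config.utr_rate * t, size=len(arr))
            for i in np.nonzero(n_sub)[0]:
                for _ in range(int(n_sub[i])):
                    others = bases.replace(arr[i], "")
                    arr[i] = others[rng.integers(3)]
            seq = "".join(arr)
        if not node.children:
            out[node.name] = seq
        for c in node.children:
            walk(c, seq, node.time)

    walk(root, ancestral, 0.0)
    return out


def translate_cds(cds: str) -> str:
    return "".join(_STANDARD_TABLE.forward_table[cds[i:i + 3]]
                   for i in range(0, len(cds), 3))


# --- annotations -----------------------------------------------------------

def evolve_annotations(root: SimNode, dag_leaves: list[str],
                       config: SimulationConfig, rng: np.random.Generator,
                       family_id: str, namespace: str,
                       pub_counter: list[int]) -> list[dict]:
    """Gain/loss evolution of direct (leaf-term) annotation sets.

    Along a branch of length t each current term is lost with probability
    1 - exp(-loss_rate * t) and Poisson(gain_rate * t) uniform ontology
    leaves are gained; relocated lineages use t multiplied by the
    interchromosomal factor.  At the speciation boundary each species
    applies one shared context pulse (the same term dooms and the same
    gain set for every lineage of that species) of time-equivalent
    magnitude ``delta``.  Gene leaves are annotated with probability
    ``annotation_sparsity``; evidence codes and PubMed ids are assigned
    with the configured sharing probabilities.
    """
    k = min(config.initial_terms, len(dag_leaves))
    state0 = set(np.array(dag_leaves)[rng.choice(len(dag_leaves), size=k,
                                                 replace=False)])
    # shared per-species context pulse
    doom_p = 1.0 - math.exp(-config.loss_rate * config.delta)
    pulses = {}
    for sp in SPECIES:
        doomed = {t for t in dag_leaves if rng.random() < doom_p}
        n_gain = rng.poisson(config.gain_rate * config.delta)
        gains = {dag_leaves[i] for i in rng.integers(0, len(dag_leaves),
                                                     size=n_gain)}
        pulses[sp] = (doomed, gains)

    dominant_code = sorted(ALLOWED_EVIDENCE_CODES)[
        rng.integers(len(ALLOWED_EVIDENCE_CODES))]
    dominant_pub = f"PM{pub_counter[0]}"
    pub_counter[0] += 1
    codes = sorted(ALLOWED_EVIDENCE_CODES)
    records: list[dict] = []

    def branch_update(terms: set, t: float, relocated: bool) -> set:
        if relocated:
            t = t * config.interchrom_multiplier
        if t <= 0:
            return set(terms)
        survive_p = math.exp(-config.loss_rate * t)
        kept = {x for x in sorted(terms) if rng.random() < survive_p}
        n_gain = rng.poisson(config.gain_rate * t)
        for i in rng.integers(0, len(dag_leaves), size=n_gain):
            kept.add(dag_leaves[i])
        return kept

    def walk(node: SimNode, terms: set, parent_time: float):
        terms = branch_update(terms, node.time - parent_time, node.relocated)
        if node.event == "speciation":
            for child in node.children:
                doomed, gains = pulses[child.species or "A"]
                child_terms = (terms - doomed) | gains
                walk(child, child_terms, node.time)
            return
        if not node.children:
            if rng.random() < config.annotation_sparsity and terms:
                for term in sorted(terms):
                    code = (dominant_code
                            if rng.random() < config.evidence_share_p
                            else codes[rng.integers(len(codes))])
                    if rng.random() < config.pub_share_p:
                        pubs = {dominant_pub}
                        if rng.random() < config.pub_extra_p:
                            pubs.add(f"PM{pub_counter[0]}")
                            pub_counter[0] += 1
                    else:
                        pubs = {f"PM{pub_counter[0]}"}
                        pub_counter[0] += 1
                    records.append({
                        "protein_id": node.name, "species": node.species,
                        "term_id": term, "evidence_code": code,
                        "pubmed_ids": ";".join(sorted(pubs)),
                    })
            return
        for child in node.children:
            walk(child, terms, node.time)

    walk(root, state0, 0.0)
    return records


# --- expression ------------------------------------------------------------

def simulate_expression(root: SimNode, config: SimulationConfig,
                        rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Brownian per-tissue expression profiles for every leaf gene.

    The ancestral profile is standard normal per tissue; each branch adds
    N(0, expr_sigma2 * t) noise per tissue, and each species applies one
    shared context-shift vector of variance expr_sigma2 * expr_delta at
    the speciation boundary.
    """
    ancestral = rng.normal(0.0, 1.0, size=config.n_tissues)
    shift = {
        sp: rng.normal(0.0, math.sqrt(config.expr_sigma2 * config.expr_delta),
                       size=config.n_tissues)
        for sp in SPECIES
    }
    out: dict[str, np.ndarray] = {}

    def walk(node: SimNode, profile: np.ndarray, parent_time: float):
        t = node.time - parent_time
        if t > 0 and config.expr_sigma2 > 0:
            profile = profile + rng.normal(
                0.0, math.sqrt(config.expr_sigma2 * t), size=config.n_tissues)
        if node.event == "speciation":
            for child in node.children:
                walk(child, profile + shift[child.species or "A"], node.time)
            return
        if not node.children:
            out[node.name] = profile
        for child in node.children:
            walk(child, profile, node.time)

    walk(root, ancestral, 0.0)
    return out


# --- the full dataset ------------------------------------------------------

def generate_dataset(config: SimulationConfig, outdir) -> SyntheticDataset:
    """Generate and write the complete, mutually consistent file set."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    obo_text = generate_obo(config, rng)
    obo_path = outdir / "ontology.obo"
    obo_path.write_text(obo_text)
    dag_leaves = {}
    for namespace in ("biological_process", "molecular_function"):
        dag = load_obo(io.StringIO(obo_text), namespace=namespace)
        dag_leaves[namespace] = sorted(
            t for t in dag.terms if not dag.children(t))

    newicks, gene_rows, truth_rows, ann_rows = [], [], [], []
    prot_fa, cds_fa = [], []
    utrs: dict[str, str] = {}
    profiles: dict[str, np.ndarray] = {}
    pub_counter = [1]
    for i in range(config.n_families):
        family_id = f"F{i:04d}"
        root = simulate_family(config, rng, family_id)
        newicks.append(family_newick(root))
        rate_mult = float(rng.lognormal(mean=0.0, sigma=config.rate_sigma))
        cds = evolve_sequences(root, config, rng, rate_mult)
        utrs.update(evolve_utrs(root, config, rng))
        for leaf in iter_leaves(root):
            gene_rows.append((leaf.name, leaf.species, leaf.chromosome))
            cds_fa.append((leaf.name, cds[leaf.name]))
            prot_fa.append((leaf.name, translate_cds(cds[leaf.name])))
        truth_rows.extend(true_pair_classes(root, config, family_id))
        for namespace in ("biological_process", "molecular_function"):
            ann_rows.extend(evolve_annotations(
                root, dag_leaves[namespace], config, rng, family_id,
                namespace, pub_counter))
        profiles.update(simulate_expression(root, config, rng))

    (outdir / "trees.nwk").write_text("\n".join(newicks) + "\n")
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene_id\tspecies\tchromosome\n")
        for row in gene_rows:
            fh.write("\t".join(row) + "\n")
    _write_fasta(outdir / "proteins.fa", prot_fa)
    _write_fasta(outdir / "cds.fa", cds_fa)
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("#protein_id\tspecies\tterm_id\tevidence_code\tpubmed_ids\n")
        for r in ann_rows:
            fh.write(f"{r['protein_id']}\t{r['species']}\t{r['term_id']}\t"
                     f"{r['evidence_code']}\t{r['pubmed_ids']}\n")

    _write_expression_files(outdir, config, rng, profiles,
                            dict(cds_fa), utrs)

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "sim_config.yaml")
    return SyntheticDataset(
        root=outdir, obo=obo_path, genes=outdir / "genes.tsv",
        trees=outdir / "trees.nwk", proteins=outdir / "proteins.fa",
        cds=outdir / "cds.fa", annotations=outdir / "annotations.tsv",
        expression=outdir / "expression.tsv", probes=outdir / "probes.fa",
        transcripts=outdir / "transcripts.fa",
        ground_truth=outdir / "ground_truth.tsv",
        config=outdir / "sim_config.yaml", truth_pairs=truth,
    )


def _write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_expression_files(outdir, config, rng, profiles, cds_by_gene, utrs):
    """Expression TSV plus probe and transcript FASTA.

    Transcripts are CDS plus the evolved 3' UTR; probes are drawn from the
    UTR.  One probeset per gene (a fraction get a second), 16
    exact-substring probes each; a configurable fraction of probesets get
    one probe copied from a different gene's transcript to exercise
    ambiguity rejection.  A fraction of tissues is emitted twice
    (duplicate samples with replicate noise).
    """
    genes = sorted(profiles)
    tissues = [f"tissue{j + 1:02d}" for j in range(config.n_tissues)]
    n_dup = int(round(config.duplicate_tissue_frac * config.n_tissues))
    dup_tissues = tissues[:n_dup]

    transcripts = [(f"{g}|{g}.t1", cds_by_gene[g] + utrs[g]) for g in genes]
    _write_fasta(outdir / "transcripts.fa", transcripts)

    probe_records = []
    rows = []
    header = tissues + dup_tissues
    for gi, gene in enumerate(genes):
        n_sets = 2 if rng.random() < config.multi_probeset_frac else 1
        for s in range(n_sets):
            ps = f"{gene}_ps{s + 1}"
            seq = utrs[gene]
            starts = rng.integers(0, len(seq) - config.probe_length + 1,
                                  size=config.probes_per_set)
            probes = [seq[st:st + config.probe_length] for st in starts]
            if rng.random() < config.ambiguous_probeset_frac and len(genes) > 1:
                other = genes[(gi + 1 + rng.integers(len(genes) - 1)) % len(genes)]
                oseq = utrs[other]
                st = rng.integers(0, len(oseq) - config.probe_length + 1)
                probes[0] = oseq[st:st + config.probe_length]
            for j, p in enumerate(probes):
                probe_records.append((f"{ps}:{j + 1}", p))
            noise = config.probe_noise_sd
            base = profiles[gene] + rng.normal(0.0, noise, size=config.n_tissues)
            values = np.exp(4.0 + base)
            dup_values = np.exp(4.0 + base[:n_dup]
                                + rng.normal(0.0, noise, size=n_dup))
            rows.append((ps, np.concatenate([values, dup_values])))
    _write_fasta(outdir / "probes.fa", probe_records)
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("probeset\t" + "\t".join(header) + "\n")
        for ps, vals in rows:
            fh.write(ps + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")
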