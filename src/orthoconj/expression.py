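"""Microarray probe mapping, two-step normalization, and expression similarity.

Expression across a shared tissue panel serves as a curator-independent
measure of gene function.  Probesets are mapped to genes by exact probe
matching, expression values are z-scored first within each tissue and then
within each probeset, probesets are averaged per gene and duplicate tissue
samples averaged, and functional similarity of a gene pair is the Pearson
correlation of the resulting profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)


@dataclass
class ProbesetMap:
    """Probeset -> gene mapping with per-probeset rejection diagnostics."""

    mapping: dict[str, str]
    rejected: dict[str, str] = field(default_factory=dict)  # probeset -> reason

    def __getitem__(self, probeset: str) -> str:
        return self.mapping[probeset]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class ExpressionMatrix:
    """Raw (s), tissue-normalized (t) and fully normalized (n) values.

    ``genes`` is the final gene x tissue matrix: probesets averaged per
    gene, then duplicate tissue samples averaged.
    """

    s: pd.DataFrame
    t: pd.DataFrame
    n: pd.DataFrame
    genes: pd.DataFrame | None = None
    dropped_tissues: list[str] = field(default_factory=list)
    dropped_rows: list[str] = field(default_factory=list)


def _read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def map_probes_to_genes(probe_fasta, transcript_fasta,
                        both_strands: bool = False) -> ProbesetMap:
    """Map probesets to genes by exact substring matching of every probe.

    Probe FASTA headers are ``probeset:index``; transcript headers are
    ``gene|transcript``.  A probeset is retained only when each of its
    probes matches at least one transcript of exactly one common gene and
    no probe matches any other gene.  Matching is forward-strand by
    default.
    """
    probes: dict[str, list[str]] = {}
    for header, seq in _read_fasta(probe_fasta).items():
        probeset = header.rsplit(":", 1)[0]
        probes.setdefault(probeset, []).append(seq)
    transcripts: dict[str, list[str]] = {}
    for header, seq in _read_fasta(transcript_fasta).items():
        gene = header.split("|", 1)[0]
        transcripts.setdefault(gene, []).append(seq)

    # exact-match lookup: index every transcript window of each probe length
    probe_lengths = sorted({len(p) for ps in probes.values() for p in ps})
    gene_hits: dict[str, set[str]] = {}
    for gene, seqs in transcripts.items():
        for s in seqs:
            for k in probe_lengths:
                for i in range(len(s) - k + 1):
                    gene_hits.setdefault(s[i:i + k], set()).add(gene)

    def probe_hits(probe: str) -> set[str]:
        variants = [probe] if not both_strands else [probe, reverse_complement(probe)]
        out: set[str] = set()
        for v in variants:
            out |= gene_hits.get(v, set())
        return out

    mapping: dict[str, str] = {}
    rejected: dict[str, str] = {}
    for probeset in sorted(probes):
        per_probe_genes = [probe_hits(p) for p in probes[probeset]]
        union = set().union(*per_probe_genes)
        if not union:
            rejected[probeset] = "no probe matches any transcript"
        elif len(union) > 1:
            rejected[probeset] = f"probes hit multiple genes: {sorted(union)}"
        elif any(not hits for hits in per_probe_genes):
            rejected[probeset] = "some probes match no transcript"
        else:
            mapping[probeset] = next(iter(union))
    return ProbesetMap(mapping=mapping, rejected=rejected)


def _zscore_columns(df: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Population z-score per column; zero-variance columns are dropped."""
    mu = df.mean(axis=0)
    sigma = df.std(axis=0, ddof=0)
    bad = list(df.columns[sigma == 0])
    if bad:
        log.warning("dropping %d constant column(s): %s", len(bad), bad[:5])
        df = df.drop(columns=bad)
        mu, sigma = mu.drop(bad), sigma.drop(bad)
    return (df - mu) / sigma, bad


def normalize_two_step(matrix: pd.DataFrame,
                       probeset_map: ProbesetMap | None = None,
                       tissues: list[str] | None = None) -> ExpressionMatrix:
    """The two-step z-score normalization, then per-gene collapsing.

    Step 1 forces every tissue column to mean 0, sd 1 (t_ij); step 2
    forces every probeset row of t to mean 0, sd 1 (n_ij).  Population
    (divide-by-N) standard deviations are used throughout.  Afterwards,
    probesets mapping to the same gene are averaged, the columns are
    restricted to ``tissues`` when given, and duplicate tissue samples
    (repeated column names) are averaged, in that order of row/column
    operations: normalize -> average probesets -> average duplicates.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 tissues")
    if matrix.isna().any().any():
        na_rows = matrix.index[matrix.isna().any(axis=1)]
        log.warning("dropping %d row(s) with missing values", len(na_rows))
        matrix = matrix.drop(index=na_rows)
    s = matrix.astype(float)
    t, dropped_tissues = _zscore_columns(s)
    n_t, dropped_rows = _zscore_columns(t.T)
    n = n_t.T

    if probeset_map is not None:
        keep = [p for p in n.index if p in probeset_map.mapping]
        genes = n.loc[keep].groupby(
            [probeset_map.mapping[p] for p in keep]
        ).mean()
    else:
        genes = n.copy()
    if tissues is not None:
        cols = [c for c in genes.columns if c in set(tissues)]
        genes = genes[cols]
    # duplicate tissue samples share a column name; average them
    genes = genes.T.groupby(level=0).mean().T
    return ExpressionMatrix(s=s, t=t, n=n, genes=genes,
                            dropped_tissues=dropped_tissues,
                            dropped_rows=dropped_rows)


def expression_similarity(profile_p, profile_q, tissue_set=None,
                          metric: str = "pearson") -> float:
    """Similarity of two expression profiles over a tissue set.

    Pearson correlation by default; ``metric='euclidean'`` returns the
    negative Euclidean distance as an alternative similarity.  Returns NaN
    when either restricted profile has zero variance.
    """
    p = pd.Series(profile_p, dtype=float)
    q = pd.Series(profile_q, dtype=float)
    if tissue_set is not None:
        cols = [c for c in p.index if c in set(tissue_set)]
        if len(cols) < 3:
            raise ValueError("need at least 3 shared tissues")
        p, q = p[cols], q[cols]
    if metric == "euclidean":
        return -float(np.linalg.norm(p.values - q.values))
    if metric != "pearson":
        raise ValueError(f"unknown metric {metric!r}")
    if np.std(p.values) == 0 or np.std(q.values) == 0:
        return float("nan")
    return float(np.corrcoef(p.values, q.values)[0, 1])


def read_expression_tsv(path) -> pd.DataFrame:
    """Probeset x tissue TSV; the header row of tissue names may repeat."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    # pandas mangles duplicate headers into name.1, name.2, ...; undo that
    df.columns = [c.split(".")[0] if c.split(".")[-1].isdigit() else c
                  for c in df.columns]
    return df
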