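"""Family-based resampling analysis (best ortholog vs. best paralog).

For each gene family, one annotated *target* protein with at least one
annotated ortholog and one annotated paralog is drawn uniformly at random.
The comparison ortholog is the annotated ortholog with the highest sequence
identity to the target (any orthology cardinality qualifies).  The family
contributes a single count to a 2x2 table: the row records whether some
annotated paralog exceeds that ortholog's identity, and the column whether
the best paralog's functional similarity exceeds the ortholog's
(functional-similarity ties credit the ortholog).  The procedure is
repeated over many replicates with fresh random targets, and per-cell
means +/- standard errors are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homology import ORTHOLOG_CLASSES, PARALOG_CLASSES

ROWS = ("paralog_higher_identity", "ortholog_higher_identity")
COLS = ("paralog_higher_fs", "ortholog_higher_fs")


@dataclass
class FamilyCountsTable:
    """Across-replicate summary of the per-family 2x2 counts."""

    mean: pd.DataFrame  # rows ROWS, columns COLS
    se: pd.DataFrame
    replicates: list[pd.DataFrame]
    #: row-conditional percentages (mean +/- SE across replicates), e.g.
    #: percent of ortholog-higher-identity families in which the ortholog
    #: also had the higher functional similarity
    percentages: pd.DataFrame = field(default=None)


def _fs_column(namespace: str) -> str:
    return {"biological_process": "fs_BP", "molecular_function": "fs_MF"}[namespace]


class _FamilyView:
    """Per-family adjacency: annotated orthologs/paralogs of each protein."""

    def __init__(self, pair_rows: pd.DataFrame, fs_col: str):
        self.orthologs: dict[str, list[str]] = {}
        self.paralogs: dict[str, list[str]] = {}
        self.identity: dict[tuple[str, str], float] = {}
        self.fs: dict[tuple[str, str], float] = {}
        for r in pair_rows.itertuples():
            fs = getattr(r, fs_col)
            if pd.isna(fs) or pd.isna(r.identity):
                continue  # pair not measurable in this namespace
            key = ((r.gene_a, r.gene_b) if r.gene_a <= r.gene_b
                   else (r.gene_b, r.gene_a))
            self.identity[key] = float(r.identity)
            self.fs[key] = float(fs)
            if r.cls in ORTHOLOG_CLASSES:
                self.orthologs.setdefault(r.gene_a, []).append(r.gene_b)
                self.orthologs.setdefault(r.gene_b, []).append(r.gene_a)
            elif r.cls in PARALOG_CLASSES:
                self.paralogs.setdefault(r.gene_a, []).append(r.gene_b)
                self.paralogs.setdefault(r.gene_b, []).append(r.gene_a)

    def pair_value(self, d, a, b):
        return d[(a, b) if a <= b else (b, a)]

    def eligible_targets(self) -> list[str]:
        return sorted(set(self.orthologs) & set(self.paralogs))


def eligible_targets(pair_rows: pd.DataFrame, namespace: str) -> list[str]:
    """Annotated proteins with >=1 annotated ortholog and >=1 annotated paralog.

    ``pair_rows`` is the slice of the pair table for one family; a protein
    counts as annotated here exactly when it appears in a pair with a
    functional-similarity value in the namespace.
    """
    return _FamilyView(pair_rows, _fs_column(namespace)).eligible_targets()


def run_family_replicate(families: dict[str, pd.DataFrame], namespace: str,
                         rng: np.random.Generator) -> pd.DataFrame:
    """One replicate: a 2x2 DataFrame of family counts."""
    fs_col = _fs_column(namespace)
    counts = pd.DataFrame(0, index=list(ROWS), columns=list(COLS))
    for family_id in sorted(families):
        view = _FamilyView(families[family_id], fs_col)
        targets = view.eligible_targets()
        if not targets:
            continue
        target = targets[rng.integers(len(targets))]
        # comparison ortholog: highest identity; ties go to the smallest
        # gene id (max returns the first maximum of the sorted list)
        orthologs = sorted(view.orthologs[target])
        best_orth = max(orthologs,
                        key=lambda g: view.pair_value(view.identity, target, g))
        orth_ident = view.pair_value(view.identity, target, best_orth)
        orth_fs = view.pair_value(view.fs, target, best_orth)
        paralogs = sorted(view.paralogs[target])
        par_idents = [view.pair_value(view.identity, target, g) for g in paralogs]
        par_fss = [view.pair_value(view.fs, target, g) for g in paralogs]
        row = ROWS[0] if max(par_idents) > orth_ident else ROWS[1]
        col = COLS[0] if max(par_fss) > orth_fs else COLS[1]  # ties credit ortholog
        counts.loc[row, col] += 1
    return counts


def run_family_analysis(families: dict[str, pd.DataFrame], namespace: str,
                        n_reps: int = 100, seed: int = 0) -> FamilyCountsTable:
    """Repeat the per-family comparison over ``n_reps`` random target draws."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    reps = [run_family_replicate(families, namespace, np.random.default_rng(s))
            for s in streams]
    stack = np.stack([r.to_numpy(dtype=float) for r in reps])
    mean = pd.DataFrame(stack.mean(axis=0), index=list(ROWS), columns=list(COLS))
    if n_reps > 1:
        se_arr = stack.std(axis=0, ddof=1) / np.sqrt(n_reps)
    else:
        se_arr = np.zeros_like(stack[0])
    se = pd.DataFrame(se_arr, index=list(ROWS), columns=list(COLS))

    # row-conditional percentages per replicate, then mean +/- SE
    pct_rows = []
    for r in reps:
        arr = r.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * arr / arr.sum(axis=1, keepdims=True)
        pct_rows.append(pct)
    pstack = np.stack(pct_rows)
    with warnings.catch_warnings():
        # a row absent from every replicate yields an all-NaN percentage
        warnings.simplefilter("ignore", RuntimeWarning)
        pmean = np.nanmean(pstack, axis=0)
        pse = (np.nanstd(pstack, axis=0, ddof=1) / np.sqrt(n_reps)
               if n_reps > 1 else np.zeros_like(pmean))
    percentages = pd.DataFrame(
        {f"{c}_pct": pmean[:, j] for j, c in enumerate(COLS)}
        | {f"{c}_pct_se": pse[:, j] for j, c in enumerate(COLS)},
        index=list(ROWS),
    )
    return FamilyCountsTable(mean=mean, se=se, replicates=reps,
                             percentages=percentages)


def split_pair_table_by_family(pair_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {fid: sub for fid, sub in pair_table.groupby("family_id")}
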