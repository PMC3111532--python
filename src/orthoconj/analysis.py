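"""Pair-level analysis: binned similarity curves, class comparisons, trends.

The central object is a pandas DataFrame of homologous pairs ("pair
table") with one row per unordered pair and columns

    gene_a, gene_b, cls, family_id, apparent, identity, fs_BP, fs_MF,
    expr_corr, dn_ds, ds, same_chromosome

A measurement column is NaN when the pair does not qualify for that
measure (e.g. one member unannotated in that namespace).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .homology import WITHIN_SPECIES_CLASSES

log = logging.getLogger(__name__)

#: Default identity bin edges: 0.50 to 1.00 in steps of 0.05.
DEFAULT_IDENTITY_EDGES = tuple(np.round(np.arange(0.50, 1.0001, 0.05), 2))


@dataclass
class BinnedCurve:
    """Per-bin count, mean and standard error of y along a divergence axis.

    Bins are half-open [lo, hi); the last bin is closed.  SE is the sample
    standard deviation over sqrt(n); bins with n = 1 report SE 0 and are
    flagged.
    """

    edges: tuple
    x_variable: str
    y_variable: str
    table: pd.DataFrame  # columns: lo, hi, n, mean, se, se_flagged

    def __len__(self) -> int:
        return len(self.table)


def assemble_pair_table(pairs, seq_df=None, fs_df=None, expr_df=None,
                        gene_table=None) -> pd.DataFrame:
    """Inner-join classification with the per-pair measurements.

    ``seq_df`` has columns gene_a, gene_b, identity (optionally dn_ds, ds);
    ``fs_df`` gene_a, gene_b, namespace, fs; ``expr_df`` gene_a, gene_b,
    expr_corr.  Gene pairs are keyed on the sorted (gene_a, gene_b) tuple.
    ``same_chromosome`` is defined only for within-species pairs.
    """
    rows = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "cls": p.cls,
         "family_id": p.family_id, "apparent": p.apparent}
        for p in pairs
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no homolog pairs supplied")
    if df.duplicated(["gene_a", "gene_b"]).any():
        dup = df[df.duplicated(["gene_a", "gene_b"])].iloc[0]
        raise ValueError(f"duplicate pair rows for ({dup.gene_a}, {dup.gene_b})")

    def keyed(frame):
        frame = frame.copy()
        lo = frame[["gene_a", "gene_b"]].min(axis=1)
        hi = frame[["gene_a", "gene_b"]].max(axis=1)
        frame["gene_a"], frame["gene_b"] = lo, hi
        return frame

    df = keyed(df)
    if seq_df is not None:
        df = df.merge(keyed(seq_df), on=["gene_a", "gene_b"], how="inner")
    if fs_df is not None:
        wide = keyed(fs_df).pivot_table(index=["gene_a", "gene_b"],
                                        columns="namespace", values="fs")
        wide = wide.rename(columns={"biological_process": "fs_BP",
                                    "molecular_function": "fs_MF"}).reset_index()
        df = df.merge(wide, on=["gene_a", "gene_b"], how="left")
    for col in ("fs_BP", "fs_MF"):
        if col not in df.columns:
            df[col] = np.nan
    if expr_df is not None:
        df = df.merge(keyed(expr_df), on=["gene_a", "gene_b"], how="left")
    if "expr_corr" not in df.columns:
        df["expr_corr"] = np.nan
    if gene_table is not None:
        same = []
        for _, r in df.iterrows():
            ga, gb = gene_table.get(r.gene_a), gene_table.get(r.gene_b)
            if ga is None or gb is None or ga.species != gb.species:
                same.append(np.nan)
            else:
                same.append(ga.chromosome == gb.chromosome)
        df["same_chromosome"] = same
        df["species_a"] = [gene_table[g].species if g in gene_table else None
                           for g in df.gene_a]
        df["species_b"] = [gene_table[g].species if g in gene_table else None
                           for g in df.gene_b]
    for cls, n in df.groupby("cls").size().items():
        log.info("pair table: %d %s pairs", n, cls)
    return df


def _bin_index(x: np.ndarray, edges) -> np.ndarray:
    """Half-open [lo, hi) bins; the last bin is closed on the right."""
    edges = np.asarray(edges, dtype=float)
    idx = np.digitize(x, edges, right=False) - 1
    idx[np.asarray(x) == edges[-1]] = len(edges) - 2
    idx[(idx < 0) | (idx > len(edges) - 2)] = -1
    return idx


def bin_curve(records: pd.DataFrame, x_variable: str, y_variable: str,
              class_filter=None, bin_edges=DEFAULT_IDENTITY_EDGES) -> BinnedCurve:
    """Mean +/- SE of ``y_variable`` per bin of ``x_variable``."""
    df = records
    if class_filter is not None:
        classes = [class_filter] if isinstance(class_filter, str) else list(class_filter)
        df = df[df.cls.isin(classes)]
    df = df.dropna(subset=[x_variable, y_variable])
    if df.empty:
        warnings.warn(f"no records for curve {y_variable} vs {x_variable}")
        table = pd.DataFrame(columns=["lo", "hi", "n", "mean", "se", "se_flagged"])
        return BinnedCurve(tuple(bin_edges), x_variable, y_variable, table)
    idx = _bin_index(df[x_variable].to_numpy(dtype=float), bin_edges)
    rows = []
    for b in range(len(bin_edges) - 1):
        y = df[y_variable].to_numpy(dtype=float)[idx == b]
        if len(y) == 0:
            continue
        se = float(np.std(y, ddof=1) / np.sqrt(len(y))) if len(y) > 1 else 0.0
        rows.append({"lo": bin_edges[b], "hi": bin_edges[b + 1], "n": len(y),
                     "mean": float(np.mean(y)), "se": se,
                     "se_flagged": len(y) == 1})
    return BinnedCurve(tuple(bin_edges), x_variable, y_variable, pd.DataFrame(rows))


def compare_classes(records: pd.DataFrame, class_a, class_b, y_variable: str,
                    identity_threshold: float = 0.0):
    """Two-sided rank-sum comparison of y between two homolog classes.

    All pairs at or above the identity threshold are pooled.  Uses the
    exact Mann-Whitney null for small tie-free samples and the
    tie-corrected normal approximation otherwise.  Returns
    ``(p_value, direction)`` where direction is the sign of
    mean(class_a) - mean(class_b).
    """
    def pick(cls):
        classes = [cls] if isinstance(cls, str) else list(cls)
        sel = records[records.cls.isin(classes)]
        if "identity" in sel.columns and identity_threshold > 0:
            sel = sel[sel.identity >= identity_threshold]
        return sel[y_variable].dropna().to_numpy(dtype=float)

    xa, xb = pick(class_a), pick(class_b)
    for name, x in (("class_a", xa), ("class_b", xb)):
        if len(x) == 0:
            raise ValueError(f"{name} has no records above the threshold")
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    direction = int(np.sign(np.mean(xa) - np.mean(xb)))
    return float(res.pvalue), direction


def trend_correlation(records: pd.DataFrame, class_filter, x_variable: str,
                      y_variable: str):
    """Spearman rank correlation of y against x over unbinned pairs.

    Returns ``(rho, p_value)``; both NaN when x or y is constant.
    """
    df = records
    if class_filter is not None:
        classes = [class_filter] if isinstance(class_filter, str) else list(class_filter)
        df = df[df.cls.isin(classes)]
    df = df.dropna(subset=[x_variable, y_variable])
    if len(df) < 3:
        raise ValueError("need at least 3 records for a trend test")
    x = df[x_variable].to_numpy(dtype=float)
    y = df[y_variable].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def chromosome_split_curves(records: pd.DataFrame, y_variable: str = "fs_BP",
                            bin_edges=DEFAULT_IDENTITY_EDGES,
                            x_variable: str = "identity"):
    """Within-species paralog curves split by chromosome co-residence.

    Returns ``(same_chromosome_curve, different_chromosome_curve,
    n_excluded)`` where excluded records lack a chromosome call.
    """
    df = records[records.cls.isin(WITHIN_SPECIES_CLASSES)]
    missing = df.same_chromosome.isna()
    n_excluded = int(missing.sum())
    if n_excluded:
        log.info("excluding %d within-species pairs without chromosome labels",
                 n_excluded)
    df = df[~missing]
    same = bin_curve(df[df.same_chromosome.astype(bool)], x_variable,
                     y_variable, None, bin_edges)
    diff = bin_curve(df[~df.same_chromosome.astype(bool)], x_variable,
                     y_variable, None, bin_edges)
    return same, diff, n_excluded
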