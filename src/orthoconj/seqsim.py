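"""Protein global alignment, percent identity, and dN/dS counting.

Sequence divergence between homologs is measured three ways:

* global (Needleman-Wunsch) percent identity under BLOSUM62 with affine
  gaps (open 11, extend 1; the first residue of a gap costs 12, each
  further residue 1; terminal gaps are penalized);
* dN and dS from a Nei-Gojobori-style counting estimator on the codon
  alignment implied by the protein alignment, with Jukes-Cantor correction;
* the dN/dS ratio, flagged undefined when dS = 0 and unreliable when the
  synonymous difference proportion reaches the Jukes-Cantor ceiling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = set(AMINO_ACIDS + "X")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    length: int


@dataclass(frozen=True)
class DivergenceEstimate:
    dN: float
    dS: float
    dn_ds: float  # nan when undefined
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ds_reliable: bool

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.dn_ds)


def _build_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    # X (unknown residue) scores 0 against everything
    for letter in matrix.alphabet:
        matrix["X", letter] = 0.0
        matrix[letter, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -12.0  # gap of length L costs 11 + L
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _build_aligner()


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _VALID_AA:
            raise ValueError(f"{name}: illegal amino-acid character {ch!r} at position {i}")
    return seq


def global_align(seq_a: str, seq_b: str) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Co-optimal alignments are resolved deterministically by taking the
    first alignment in the aligner's fixed traceback order, so results are
    reproducible across runs.
    """
    seq_a = _check_protein(seq_a, "seq_a")
    seq_b = _check_protein(seq_b, "seq_b")
    alignments = _ALIGNER.align(seq_a, seq_b)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best.score),
        matches=matches,
        length=len(aligned_a),
    )


def percent_identity(alignment: AlignmentResult) -> float:
    """Matching residues divided by the full alignment length (gaps included)."""
    return alignment.matches / alignment.length


def alignment_identity(seq_a: str, seq_b: str) -> float:
    return percent_identity(global_align(seq_a, seq_b))


# --- Nei-Gojobori counting -------------------------------------------------

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one codon.

    Each position contributes 1/3 site per possible single-nucleotide
    change; changes creating a stop codon count as nonsynonymous.
    """
    aa = _STANDARD_TABLE.forward_table[codon]
    syn = nonsyn = 0.0
    for i, nt in enumerate(codon):
        for base in _BASES:
            if base == nt:
                continue
            neighbor = codon[:i] + base + codon[i + 1:]
            if neighbor in _STANDARD_TABLE.stop_codons:
                nonsyn += 1.0
            elif _STANDARD_TABLE.forward_table[neighbor] == aa:
                syn += 1.0
            else:
                nonsyn += 1.0
    return syn / 3.0, nonsyn / 3.0


@lru_cache(maxsize=None)
def _codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences, averaged with equal weight
    over all mutational pathways between the two codons; pathways passing
    through a stop codon are excluded.  In the degenerate case where every
    pathway is blocked, all differences are counted as nonsynonymous."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def translate(codon):
        return _STANDARD_TABLE.forward_table.get(codon)  # None for stops

    syn = nonsyn = 0.0
    n_valid = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        path = []
        blocked = False
        for pos in order:
            step = current[:pos] + codon_b[pos] + current[pos + 1:]
            if translate(step) is None and step != codon_b:
                blocked = True
                break
            path.append((translate(current), translate(step)))
            current = step
        if blocked:
            continue
        n_valid += 1
        for aa_from, aa_to in path:
            if aa_from == aa_to:
                syn += 1.0
            else:
                nonsyn += 1.0
    if n_valid == 0:
        return 0.0, float(len(diff_pos))
    return syn / n_valid, nonsyn / n_valid


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def back_translate_alignment(cds_a: str, cds_b: str,
                             alignment: AlignmentResult) -> list[tuple[str, str]]:
    """Codon alignment implied by the protein alignment; gapped columns dropped."""
    cds_a, cds_b = cds_a.upper().replace("U", "T"), cds_b.upper().replace("U", "T")
    prot_a = alignment.aligned_a.replace("-", "")
    prot_b = alignment.aligned_b.replace("-", "")
    for name, cds, prot in (("cds_a", cds_a, prot_a), ("cds_b", cds_b, prot_b)):
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"{name}: CDS length {len(cds)} is not 3x protein length {len(prot)}"
            )
        for i in range(0, len(cds), 3):
            if cds[i:i + 3] in _STANDARD_TABLE.stop_codons:
                raise ValueError(f"{name}: internal stop codon at nucleotide {i}")
    ia = ib = 0
    codons = []
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if ca != "-" and cb != "-":
            codons.append((cds_a[3 * ia:3 * ia + 3], cds_b[3 * ib:3 * ib + 3]))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return codons


def estimate_divergence(cds_a: str, cds_b: str,
                        protein_alignment: AlignmentResult) -> DivergenceEstimate:
    """Counting estimate of dN and dS over the implied codon alignment.

    Proportions of synonymous and nonsynonymous differences are each
    Jukes-Cantor corrected.  dS is flagged unreliable (and left infinite)
    when the synonymous proportion reaches the correction's 0.75 ceiling;
    dN/dS is NaN when dS is 0 or unreliable.
    """
    codons = back_translate_alignment(cds_a, cds_b, protein_alignment)
    S = N = Sd = Nd = 0.0
    for ca, cb in codons:
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _codon_diffs(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ds_reliable = pS < 0.75
    dS = _jukes_cantor(pS) if ds_reliable else math.inf
    dN = _jukes_cantor(pN) if pN < 0.75 else math.inf
    if ds_reliable and dS > 0 and math.isfinite(dN):
        ratio = dN / dS
    else:
        ratio = math.nan
    return DivergenceEstimate(
        dN=dN, dS=dS, dn_ds=ratio,
        syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd,
        ds_reliable=ds_reliable,
    )
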