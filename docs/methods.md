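# Methods

## The statistic and the question

The package asks whether orthologs predict gene function better than
paralogs once sequence divergence is controlled for.  Function is
measured two ways: overlap of propagated ontology-term sets, and
correlation of cross-tissue expression profiles.  Divergence is global
protein identity (with dN/dS and dS as alternative axes).  The analysis
then compares homolog classes — 1:1 orthologs, one-to-many/many-to-many
orthologs, inparalogs, within-species outparalogs, between-species
outparalogs — as curves of mean similarity per identity bin.

### Term-set similarity

Annotations are restricted to curated evidence codes (IDA, IEP, IGI,
IMP, IPI, TAS, IC) and propagated: a protein's set T(p) is the union of
its annotated terms and all their ancestors via `is_a` and `part_of`
edges (configurable), excluding the namespace root.  The Biological
Process and Molecular Function namespaces never mix.  Pair similarity is
the Maryland bridge coefficient ½|T(p)∩T(q)|(1/|T(p)|+1/|T(q)|), which
is 1 only for identical non-empty sets, 0 only for disjoint ones, and
bounds the Jaccard coefficient from above.  Proteins with an empty
propagated set in a namespace are excluded from that namespace's
analysis.

Term depth (used by the depth-equalization control) is the BFS distance
from the root by default; a longest-path variant is available because
"distance from the root" is ambiguous in a DAG.

### Homolog classification

Gene trees arrive as Newick with NHX `D=Y|N` tags; untagged nodes are
labeled by species overlap (duplication iff two child subtrees share a
species).  Tags win over the overlap rule unless relabeling is forced.
For each leaf pair the class follows from the event at the last common
ancestor (LCA):

- speciation LCA, cross-species: ortholog; 1:1 iff no duplication lies
  on either path from the LCA to the leaves, otherwise
  one-to-many/many-to-many;
- duplication LCA, same species: inparalog iff the LCA's subtree
  contains a single species (the duplication postdates the split),
  otherwise within-species outparalog;
- duplication LCA, cross-species: between-species outparalog.

A cross-species pair under a duplication whose child subtrees are
species-disjoint is flagged *apparent*: such nodes usually reflect tree
error or reciprocal loss, and these pairs are merged into the 1:1
ortholog class by default (droppable instead).  A same-species pair
under a (mislabeled) speciation LCA is treated as a within-species
outparalog, since the label implies divergence no later than the split.
Because species labels are never wrong, within-species pairs can never
be confused with cross-species pairs regardless of topology errors —
the property that makes the class comparisons robust.  Classification is
verified against an independent brute-force LCA classifier on
exhaustively enumerated 4-leaf trees and random 5–6-leaf trees.

Curve analyses use 1:1 orthologs (including merged apparent ones); the
family-based analysis additionally admits one-to-many/many-to-many
orthologs.

### Sequence similarity and divergence

Needleman–Wunsch global alignment under BLOSUM62 with affine gaps: the
first residue of a gap costs 11 + 1 = 12, each further residue 1, and
terminal gaps are penalized (true global alignment).  Unknown residues
(X) score 0 against everything.  Identity is matches divided by the full
alignment length, gap columns included, with no coverage filter.
Co-optimal alignments are resolved by the aligner's deterministic
first-traceback order, fixed across runs.  Scores are checked against
exhaustive enumeration of all global alignments for short sequences.

dN and dS use a counting estimator in the Nei–Gojobori style on the
codon alignment implied by back-translating the protein alignment
(gapped columns dropped): per-codon synonymous site fractions, pathway
averaging over orderings of multi-position codon differences with
stop-passing pathways excluded, and a Jukes–Cantor correction applied to
each proportion.  dS is flagged unreliable at the correction's ceiling
(p_S ≥ 0.75) and dN/dS is undefined when dS is 0.  A maximum-likelihood
codon model is deliberately out of scope: dN/dS and dS serve only as
alternative binning axes, for which a counting estimator preserves
ordering.  The estimator is cross-checked against an independent NG86
implementation on codon pairs where the stop-pathway conventions
coincide.

### Expression similarity

Probesets map to genes only when every probe is an exact substring of
at least one transcript of exactly one common gene; a probe hitting a
second gene discards the probeset.  Matching is forward-strand by
default (`both_strands` optional).  Normalization is two z-score steps
with population (divide-by-N) standard deviations — first within each
tissue column, then within each probeset row — followed by averaging
probesets per gene, restricting to the shared tissue panel, and
averaging duplicate tissue samples, in that order.  (Whether the source
study averaged duplicates before or after restricting to shared tissues
is not documented; restricting first is this package's choice.)
Zero-variance rows/columns are dropped with a warning; missing values
are not imputed.  Pair similarity is the Pearson correlation of the
normalized profiles over at least three shared tissues (25 by default);
negative Euclidean distance is available as an alternative.

### Curves and tests

Bins are half-open [lo, hi) with the last bin closed; default identity
edges run 0.50–1.00 in 0.05 steps (bin width is not dictated by the
measures themselves; 0.05 spans the range with adequate counts).  Bin
summaries are mean ± sd/√n (SE flagged at n = 1).  Class comparisons
pool pairs above an identity threshold (0.70 by default) into a
two-sided Mann–Whitney/Wilcoxon test — exact for small tie-free samples,
tie-corrected normal approximation otherwise — reported with the sign of
the mean difference.  Trends are Spearman rank correlations over
unbinned pairs with midrank ties.  The chromosome split restricts to
within-species paralogs and compares same- versus different-chromosome
pairs; chromosome co-residence is undefined for cross-species pairs.

### Family-based resampling

Per family, one target protein is drawn uniformly from those with at
least one measurable ortholog and one measurable paralog (any paralog
type).  The comparison ortholog is the target's highest-identity
annotated ortholog (identity ties broken toward the smallest gene id);
the family then contributes one count to a 2×2 table: whether any
annotated paralog beats that ortholog's identity, by whether the best
paralog fs exceeds the ortholog's (fs ties credit the ortholog — the
conservative direction for the conjecture).  The draw is repeated (100
replicates by default) with per-replicate RNG substreams spawned from
one seed; only the target is re-drawn.  Cells report across-replicate
mean ± SE plus row-conditional percentages.

### Bias controls

Each filter is a pure contraction re-feeding the standard pipeline:
terms restricted to those annotated in both species; per-family depth
equalization (terms deeper than the smallest per-protein maximum depth
removed — never emptying a set, since every set retains a depth-1
ancestor); a per-pair publication filter in which an annotation is kept
iff it has a supporting publication id that is not the sole support of
any partner annotation (so support can be "reassigned" to distinct
publications when possible), with an inverse mode keeping only shared
support; and evidence-code filters (per-pair code matching before
propagation, or a per-protein equal-code-set variant, plus global
removal of TAS annotations).  The publication rule is deliberately one
level deep rather than a full bipartite matching solver; it reproduces
the documented edge cases and stays O(pair size).

## The synthetic-data generator

The generator emulates the statistical structure of a two-species
(human/mouse-like) comparative study at desk scale.  What it models:

- **Families** arise from a birth process of duplications (rate 0.25
  per lineage per time unit) around a single speciation at t = 1 of a
  total tree depth 2; every lineage alive at the split yields one copy
  per species.  Duplicated copies relocate to a random other chromosome
  with probability 0.3.  Oversized families (> 24 leaves) are redrawn.
- **Sequences**: 120 codons; per codon, amino-acid replacements are
  Poisson (0.06 per codon-time; each jump uniform over the 19 other
  amino acids) and synonymous codon changes Poisson (0.12).  With these
  rates same-age 1:1 orthologs average ≈ 0.87 identity, matching the
  reported identity of annotated mammalian 1:1 orthologs.  A lognormal
  per-family rate multiplier (σ = 0.7) spreads ortholog identity across
  the 0.5–1.0 axis, as gene-specific rates do in real data.
- **Annotations** evolve as per-term exponential loss (rate 0.25) plus
  Poisson gains (rate 1.5) of uniform ontology leaf terms, from an
  ancestral set of 8 leaf terms per namespace, on a generated two-
  namespace ontology (150 terms each, with diamond motifs and one
  obsolete term).  Evidence codes and PubMed ids are drawn with
  family-level sharing probabilities (0.7 / 0.5) so the publication and
  evidence filters have structure to act on.
- **The species context shift δ** (default 1.0 time-equivalents) is the
  planted effect: at the speciation boundary each species applies *one
  shared* gain/loss pulse to every lineage crossing into it.  Sharing is
  the point — same-species pairs (inparalogs, within-species
  outparalogs) inherit identical pulses and so accrue no extra
  divergence from them, while every cross-species pair is separated by
  two independent pulses.  This makes "equal age ⇒ equal expected
  similarity" literally true within a species and plants the observed
  ordering: inparalogs > within-species outparalogs > cross-species
  pairs at matched identity, and a flat ortholog curve (all 1:1
  orthologs are the same age).
- **The interchromosomal multiplier** (default 3) scales annotation-
  divergence time on every branch of a relocated copy's subtree,
  planting the same-chromosome > different-chromosome paralog contrast.
- **Expression**: ancestral N(0,1) profiles over 25 tissues, Brownian
  drift (σ² = 0.3 per time) along branches, one shared per-species
  context vector at the split (variance σ²·δ), exponentiated into
  intensity scale with small probeset-level noise.  Transcripts are the
  CDS plus a fast-evolving 3′ region (150 nt, 0.5 substitutions per
  site-time) from which the 16 probes per probeset are drawn — as with
  real 3′-biased arrays, this keeps probes gene-specific except between
  very young duplicates; a configurable fraction of probesets get one
  cross-gene probe to exercise rejection, and a fraction of tissues is
  emitted in duplicate.
- 60 % of genes are annotated per namespace.  This is above the
  genome-wide annotated fraction in the real databases; it keeps every
  class populated in a 500-family study, which is the scale the test
  suite runs at.

What the generator does *not* emulate: realistic GO topology, gene loss
and pseudogenization, indels (sequences stay equal length — alignment
gaps are exercised by the oracle tests instead), cross-hybridization,
and array batch effects.  Passing parameter-recovery tests therefore
show that the pipeline recovers planted effects of the hypothesized
kind, not that real data contain them.

Everything is driven by one seed through a single RNG stream; the whole
emitted file set is byte-identical across runs with equal configuration,
and classification of the emitted trees reproduces the generator's true
pair classes exactly.

## Numerical and design choices

- Population (N-denominator) standard deviations in both normalization
  steps; invariants assertable to 1e-9.
- Alignment tie-break: the aligner's deterministic first traceback
  (the choice affects only which co-optimal alignment is reported,
  never the score).
- Half-open bins, last bin closed; records below 0.50 identity are
  excluded from class-comparison curves (1:1 orthologs become too
  sparse there) but not from paralog-only analyses.
- The rank-sum comparison pools pairs above the identity threshold
  rather than testing bin-by-bin.
- Family-analysis tie rules (identity ties → lexicographic; fs ties →
  ortholog) are fixed and configurable; only targets are re-drawn
  across replicates.
- The type-I control for the planted-effect tests regenerates the data
  with δ = 0, multiplier = 1 *and* homogeneous sequence rates: with
  heterogeneous rates, classes genuinely differ in age at matched
  identity, which would confound the intended null.  Matched-bin
  contrasts are Holm-corrected.
- Desk-scale problem sizes: 500 families for parameter recovery, 2000
  simulations for test calibration, exhaustive oracles at ≤ 6 leaves /
  length ≤ 6 / n ≤ 8.

## Known limitations

- The counting dN/dS estimator saturates near p = 0.75 and is reported
  as unreliable there; deep outparalog comparisons on the dS axis
  should be read accordingly.
- Same-species pairs under inconsistently labeled speciation LCAs are
  assigned to the within-species outparalog class rather than rejected;
  datasets with many unreliable tags should use forced species-overlap
  relabeling.
- The per-pair publication filter is a one-level feasibility rule, not
  a maximum matching; contrived multi-way sharing patterns could in
  principle retain slightly less than optimal.
- Expression similarity uses Pearson correlation on doubly z-scored
  values; alternatives (Euclidean) are offered but rank-based measures
  are not.
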