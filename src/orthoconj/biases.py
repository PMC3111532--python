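"""Robustness filters for annotation-driven biases.

Each filter is a pure contraction of the annotation data (it never adds
terms or pairs); the standard curve pipeline is then re-run on the
filtered data.  Filters cover: species-specific study bias, uneven
annotation depth, shared-publication bias, and evidence-code bias.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ontology import (ALLOWED_EVIDENCE_CODES, AnnotationSet,
                       OntologyDAG, propagate_terms)


@dataclass
class FilterReport:
    filter_name: str
    records_before: int
    records_after: int
    pairs_before: int = 0
    pairs_after: int = 0

    def __post_init__(self):
        if self.records_after > self.records_before:
            raise ValueError("a bias filter can never add records")


def filter_shared_species_terms(annotation_sets: dict[str, AnnotationSet],
                                species_of: dict[str, str]):
    """Keep only terms annotated in at least one protein of *each* species.

    Operates on propagated sets.  Proteins whose sets empty out are
    dropped.  Idempotent.
    """
    per_species: dict[str, set[str]] = {}
    for pid, aset in annotation_sets.items():
        per_species.setdefault(species_of[pid], set()).update(aset.terms)
    if per_species:
        shared = set.intersection(*per_species.values())
    else:
        shared = set()
    out = {}
    for pid, aset in annotation_sets.items():
        kept = frozenset(aset.terms & shared)
        if kept:
            out[pid] = AnnotationSet(pid, kept, aset.namespace)
    report = FilterReport(
        "shared_species_terms",
        records_before=sum(len(a.terms) for a in annotation_sets.values()),
        records_after=sum(len(a.terms) for a in out.values()),
    )
    return out, report


def truncate_family_depth(family_sets: dict[str, AnnotationSet],
                          depths: dict[str, int]):
    """Equalize annotation specificity within a family.

    Each protein's maximal term depth is computed; terms deeper than the
    minimum of those maxima are removed from every protein in the family.
    Because every propagated set contains a term at depth 1 or more and
    the cutoff is at least the smallest maximum, no set is emptied.
    """
    if len(family_sets) < 2:
        return dict(family_sets), FilterReport(
            "family_depth", sum(len(a.terms) for a in family_sets.values()),
            sum(len(a.terms) for a in family_sets.values()))
    max_depths = {pid: max(depths[t] for t in aset.terms)
                  for pid, aset in family_sets.items()}
    cutoff = min(max_depths.values())
    out = {
        pid: AnnotationSet(pid,
                           frozenset(t for t in aset.terms if depths[t] <= cutoff),
                           aset.namespace)
        for pid, aset in family_sets.items()
    }
    report = FilterReport(
        "family_depth",
        records_before=sum(len(a.terms) for a in family_sets.values()),
        records_after=sum(len(a.terms) for a in out.values()),
    )
    return out, report


def exclude_same_publication_pairs(records_p, records_q, mode: str = "separate"):
    """Per-pair publication filter on un-propagated annotation records.

    In ``separate`` mode an annotation is retained iff it can be certified
    by a publication identifier that is not the sole support of any of the
    partner's annotations — so when both sides can be assigned distinct
    PubMed ids, both are kept.  ``same_only`` inverts the filter: an
    annotation is retained iff it shares at least one publication id with
    the partner's support.
    """
    if mode not in ("separate", "same_only"):
        raise ValueError(f"unknown mode {mode!r}")

    def sole_supports(records):
        return {next(iter(r.publication_ids))
                for r in records if len(r.publication_ids) == 1}

    def union_pubs(records):
        out = set()
        for r in records:
            out |= r.publication_ids
        return out

    if mode == "separate":
        forced_q = sole_supports(records_q)
        forced_p = sole_supports(records_p)
        kept_p = [r for r in records_p if r.publication_ids - forced_q]
        kept_q = [r for r in records_q if r.publication_ids - forced_p]
    else:
        pubs_q = union_pubs(records_q)
        pubs_p = union_pubs(records_p)
        kept_p = [r for r in records_p if r.publication_ids & pubs_q]
        kept_q = [r for r in records_q if r.publication_ids & pubs_p]
    return kept_p, kept_q


def restrict_evidence(records_p, records_q=None, mode: str = "drop_TAS",
                      per_protein: bool = False):
    """Evidence-code filters.

    ``drop_TAS`` removes Traceable Author Statement annotations globally
    (applied to a single record list, before propagation).  ``same_code``
    is a per-pair filter: an annotation is retained iff its evidence code
    is also used by the partner (per-term matching of codes across the
    pair); with ``per_protein`` the pair is kept in full only when the two
    proteins' code sets are identical, and dropped entirely otherwise.
    """
    for rec in list(records_p) + (list(records_q) if records_q else []):
        if rec.evidence_code not in ALLOWED_EVIDENCE_CODES:
            raise ValueError(f"unknown evidence code {rec.evidence_code!r}")
    if mode == "drop_TAS":
        return [r for r in records_p if r.evidence_code != "TAS"]
    if mode != "same_code":
        raise ValueError(f"unknown mode {mode!r}")
    if records_q is None:
        raise ValueError("same_code mode is pairwise; records_q required")
    codes_p = {r.evidence_code for r in records_p}
    codes_q = {r.evidence_code for r in records_q}
    if per_protein:
        if codes_p == codes_q:
            return list(records_p), list(records_q)
        return [], []
    kept_p = [r for r in records_p if r.evidence_code in codes_q]
    kept_q = [r for r in records_q if r.evidence_code in codes_p]
    return kept_p, kept_q


def pair_term_sets(records_p, records_q, dag: OntologyDAG):
    """Propagated per-pair term sets from (possibly filtered) records."""
    terms_p = propagate_terms({r.term_id for r in records_p if r.term_id in dag}, dag)
    terms_q = propagate_terms({r.term_id for r in records_q if r.term_id in dag}, dag)
    return terms_p, terms_q
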