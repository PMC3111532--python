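"""Set-overlap functional similarity between propagated term sets.

The headline statistic is the Maryland bridge coefficient

    fs(p, q) = |T(p) & T(q)| / 2 * (1/|T(p)| + 1/|T(q)|),

the average of the fraction of p's terms recovered by transferring q's
terms and vice versa.  It is bounded by [0, 1], equals 1 only for equal
non-empty sets, 0 only for disjoint sets, and dominates the Jaccard
coefficient |&|/|union| everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    size_p: int
    size_q: int
    intersection: int


def maryland_bridge(terms_p, terms_q) -> SimilarityScore:
    """Maryland bridge functional similarity of two non-empty term sets."""
    terms_p, terms_q = set(terms_p), set(terms_q)
    if not terms_p or not terms_q:
        raise ValueError("functional similarity requires non-empty term sets; "
                         "unannotated proteins must be excluded upstream")
    inter = len(terms_p & terms_q)
    value = 0.5 * inter * (1.0 / len(terms_p) + 1.0 / len(terms_q))
    return SimilarityScore(value=value, size_p=len(terms_p), size_q=len(terms_q),
                           intersection=inter)


def jaccard(terms_p, terms_q) -> float:
    """Intersection over union of two non-empty term sets."""
    terms_p, terms_q = set(terms_p), set(terms_q)
    if not terms_p or not terms_q:
        raise ValueError("Jaccard similarity requires non-empty term sets")
    return len(terms_p & terms_q) / len(terms_p | terms_q)
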