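"""Descriptor co-occurrence similarity between a seed disease term and every
other MeSH descriptor in the corpus.

With X the publication set of the seed descriptor and Y that of another
descriptor, five measures of occurrence similarity are supported:

* cosine  = |X∩Y| / sqrt(|X|·|Y|)
* dice    = 2|X∩Y| / (|X| + |Y|)
* jaccard = |X∩Y| / |X∪Y|
* simpson = |X∩Y| / min(|X|, |Y|)
* pmi     = ln[ P(X,Y) / (P(X)·P(Y)) ], probabilities over the corpus of N
  publications

The four set-overlap measures are bounded in [0, 1] and satisfy
jaccard ≤ dice ≤ cosine ≤ simpson on every valid count vector.  PMI is
unbounded and undefined when the terms never co-occur.  The log base of PMI
is natural; ranking is invariant to the base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .corpus import Corpus
from .exceptions import UndefinedSimilarityError, UnknownTermError, ValidationError

MEASURES: tuple[str, ...] = ("cosine", "dice", "jaccard", "simpson", "pmi")

__all__ = [
    "MEASURES",
    "CooccurrenceCounts",
    "TermSimilarity",
    "cooccurrence",
    "similarity",
    "rank_terms",
]


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Publication counts for a seed/other descriptor pair.

    ``n_x`` = |X| (seed), ``n_y`` = |Y| (other), ``n_xy`` = |X∩Y|,
    ``n_total`` = N, the corpus size used for PMI probabilities.
    """

    n_x: int
    n_y: int
    n_xy: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_xy <= min(self.n_x, self.n_y)):
            raise ValidationError(
                f"inconsistent counts: n_xy={self.n_xy} exceeds "
                f"min(n_x={self.n_x}, n_y={self.n_y}) or is negative"
            )
        if max(self.n_x, self.n_y) > self.n_total:
            raise ValidationError(
                f"counts exceed corpus size: n_x={self.n_x}, n_y={self.n_y}, "
                f"n_total={self.n_total}"
            )


@dataclass(frozen=True)
class TermSimilarity:
    term: str
    measure: str
    value: float


def _corpus_size_for_terms(corpus: Corpus) -> int:
    # Restricted corpora measure term occurrence over publications that carry
    # at least one descriptor; unrestricted ones over every publication known
    # to either index (keeps n_y <= N when annotations cover unlinked pubs).
    if corpus.restricted:
        return len(corpus.terms_of_pub)
    return len(corpus.genes_of_pub.keys() | corpus.terms_of_pub.keys())


def cooccurrence(corpus: Corpus, seed: str, other: str) -> CooccurrenceCounts:
    """Count publications bearing the seed term, the other term, and both."""
    if seed not in corpus.pubs_of_term:
        raise UnknownTermError(f"seed descriptor {seed!r} not in corpus term index")
    x = corpus.pubs_of_term[seed]
    y = corpus.pubs_of_term.get(other, set())
    return CooccurrenceCounts(
        n_x=len(x),
        n_y=len(y),
        n_xy=len(x & y),
        n_total=_corpus_size_for_terms(corpus),
    )


def similarity(counts: CooccurrenceCounts, measure: str) -> float:
    """Evaluate one similarity measure on a count vector."""
    if measure not in MEASURES:
        raise ValidationError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    n_x, n_y, n_xy, n_total = counts.n_x, counts.n_y, counts.n_xy, counts.n_total
    if n_x == 0:
        raise UndefinedSimilarityError("seed term occurs in zero publications")

    if measure == "cosine":
        denom = math.sqrt(n_x * n_y)
    elif measure == "dice":
        denom = n_x + n_y
        n_xy = 2 * n_xy
    elif measure == "jaccard":
        denom = n_x + n_y - counts.n_xy
    elif measure == "simpson":
        denom = min(n_x, n_y)
    else:  # pmi
        if counts.n_xy == 0:
            raise UndefinedSimilarityError(
                "PMI is undefined for terms that never co-occur"
            )
        return math.log(counts.n_xy * n_total / (n_x * n_y))

    if denom == 0:
        raise UndefinedSimilarityError(
            f"{measure} similarity has a zero denominator (n_x={n_x}, n_y={n_y})"
        )
    return n_xy / denom


def rank_terms(
    corpus: Corpus, seed: str, measure: str, max_terms: int
) -> list[TermSimilarity]:
    """Rank corpus descriptors by similarity to the seed term.

    The seed itself is always rank 1 (self-similarity, exactly 1 for the
    bounded measures).  Descriptors never co-occurring with the seed are
    excluded.  Remaining descriptors sort by descending similarity, ties by
    ascending lexicographic descriptor, and the list is truncated to
    ``max_terms`` entries including the seed.
    """
    if max_terms < 1:
        raise ValidationError(f"max_terms must be >= 1, got {max_terms}")
    seed_value = similarity(cooccurrence(corpus, seed, seed), measure)
    ranked = [TermSimilarity(seed, measure, seed_value)]

    scored: list[TermSimilarity] = []
    for term in corpus.pubs_of_term:
        if term == seed:
            continue
        counts = cooccurrence(corpus, seed, term)
        if counts.n_xy == 0:
            continue
        scored.append(TermSimilarity(term, measure, similarity(counts, measure)))
    scored.sort(key=lambda ts: (-ts.value, ts.term))
    ranked.extend(scored)
    return ranked[:max_terms]
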