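"""Nested MeSH term-set construction and recall-based best-set selection.

Starting from the similarity-ranked descriptor list, candidate query sets are
built incrementally: set #0 is the seed descriptor alone, set #k adds the
next most similar descriptor to set #(k-1).  Each set acts as an OR-query
over exact descriptor matches (no tree explosion).  The set whose gathered,
score-ranked gene list achieves the highest recall-at-k — with k fixed at the
seed-only baseline's gene count so differently sized lists compare fairly —
is selected as the disease-related term set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .corpus import Corpus, ValidationSet
from .exceptions import ValidationError
from .scoring import RankedGeneList, rank_genes, score_genes
from .similarity import TermSimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "TermSet",
    "SelectionResult",
    "build_nested_sets",
    "retrieve_publications",
    "genes_from_publications",
    "recall_at_k",
    "best_index",
    "select_best_set",
]


@dataclass(frozen=True)
class TermSet:
    """An ordered, duplicate-free descriptor set used as an OR-query.

    ``index`` labels the nesting level: 0 is the seed-only baseline, k the
    seed plus the top-k similar descriptors (so ``index == len(terms) - 1``).
    """

    terms: tuple[str, ...]
    index: int

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("a term set must contain at least the seed term")
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError(f"duplicate descriptors in term set: {self.terms}")
        if self.index != len(self.terms) - 1:
            raise ValidationError(
                f"term set index {self.index} inconsistent with size {len(self.terms)}"
            )

    @property
    def seed(self) -> str:
        return self.terms[0]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class SelectionResult:
    best: TermSet
    recall: float
    k: int
    table: pd.DataFrame  # one row per candidate set


def build_nested_sets(
    ranked: Sequence[TermSimilarity], max_size: int
) -> list[TermSet]:
    """Build the nested candidate sets #0..#min(max_size, len(ranked)-1)."""
    if not ranked:
        raise ValidationError("cannot build term sets from an empty ranked list")
    terms = [ts.term for ts in ranked]
    limit = min(max_size, len(terms) - 1)
    return [TermSet(tuple(terms[: k + 1]), index=k) for k in range(max(limit, 0) + 1)]


def retrieve_publications(corpus: Corpus, term_set: TermSet) -> set[int]:
    """OR-query: union of each descriptor's publication set (exact match).

    Descriptors absent from the corpus contribute the empty set, mirroring a
    no-hit query clause.
    """
    pmids: set[int] = set()
    for term in term_set.terms:
        pmids |= corpus.pubs_of_term.get(term, set())
    return pmids


def genes_from_publications(corpus: Corpus, pmids: set[int]) -> set[int]:
    """Gather every gene linked to any of the given publications."""
    genes: set[int] = set()
    for pmid in pmids:
        genes |= corpus.genes_of_pub.get(pmid, set())
    return genes


def recall_at_k(
    ranked_genes: RankedGeneList, k: int, validation: ValidationSet
) -> float:
    """Fraction of the validation set found among the top-k ranked genes."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > len(ranked_genes):
        logger.warning(
            "recall_at_k: k=%d exceeds ranked list length %d; using full list",
            k,
            len(ranked_genes),
        )
        k = len(ranked_genes)
    hits = validation.genes.intersection(ranked_genes.top(k))
    return len(hits) / len(validation)


def best_index(recalls: Sequence[float]) -> int:
    """Index of the maximum recall; ties resolve to the smallest index
    (the cheaper, smaller term set)."""
    if len(recalls) == 0:
        raise ValidationError("empty recall sequence")
    best = 0
    for i, value in enumerate(recalls):
        if value > recalls[best]:
            best = i
    return best


def select_best_set(
    corpus: Corpus,
    sets: Sequence[TermSet],
    validation: ValidationSet,
    scorer: str = "wls",
) -> SelectionResult:
    """Evaluate every candidate term set and return the recall-maximizing one.

    The rank cutoff k is the number of genes gathered by the seed-only
    baseline (set #0); every candidate's gene list is ranked with ``scorer``
    and its recall-at-k against ``validation`` recorded.  Ties go to the
    smaller set.
    """
    if not sets:
        raise ValidationError("no candidate term sets given")
    baseline_genes = genes_from_publications(
        corpus, retrieve_publications(corpus, sets[0])
    )
    if not baseline_genes:
        raise ValidationError(
            "the seed-only baseline retrieves zero genes; the recall cutoff k "
            "is undefined"
        )
    k = len(baseline_genes)

    rows = []
    recalls = []
    for term_set in sets:
        pmids = retrieve_publications(corpus, term_set)
        genes = genes_from_publications(corpus, pmids)
        ranked = rank_genes(score_genes(corpus, pmids, scorer))
        recall = recall_at_k(ranked, k, validation)
        recalls.append(recall)
        rows.append(
            {
                "set_index": term_set.index,
                "terms": "|".join(term_set.terms),
                "n_pubs": len(pmids),
                "n_genes": len(genes),
                "recall": recall,
            }
        )
    winner = best_index(recalls)
    return SelectionResult(
        best=sets[winner],
        recall=recalls[winner],
        k=k,
        table=pd.DataFrame(rows),
    )
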