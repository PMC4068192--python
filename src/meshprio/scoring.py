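"""Gene prioritization scores over a retrieved disease publication set.

Four methods are implemented.  The weighted literature score of gene *i*,

    WLS_i = sum over retrieved publications j of f(i,j) * 1/P_j,

splits each publication's unit of evidence equally among the P_j genes it
cites, so a many-gene "-omics" paper contributes little per gene while a
focused single-gene study contributes a full unit.  The comparison methods
are the raw retrieved-publication count, a modified TF-IDF

    TFIDF_i = (retrieved count of i) * ln(n / L_i)

with n the total corpus size and L_i gene i's total corpus publication
count, and an upper-tail hypergeometric enrichment p-value with
Benjamini–Hochberg FDR adjustment.

Sums run over the retrieved (disease) publication set, while P_j, L_i and n
are global corpus quantities.  Genes with no link among the retrieved
publications are absent from the output: gathering precedes scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .corpus import Corpus
from .exceptions import ValidationError

METHODS: tuple[str, ...] = ("wls", "count", "tfidf", "hypergeom")
#: methods ranked ascending (smaller is better); all others rank descending
ASCENDING_METHODS: frozenset[str] = frozenset({"hypergeom"})

__all__ = [
    "METHODS",
    "GeneScore",
    "RankedGeneList",
    "weighted_literature_score",
    "publication_count_score",
    "tfidf_score",
    "hypergeometric_score",
    "bh_adjust",
    "score_genes",
    "rank_genes",
]


@dataclass(frozen=True)
class GeneScore:
    gene_id: int
    value: float
    method: str


@dataclass(frozen=True)
class RankedGeneList:
    """An ordered prioritization under one scoring method (ranks 1-based)."""

    entries: tuple[GeneScore, ...]
    method: str

    @property
    def gene_ids(self) -> list[int]:
        return [entry.gene_id for entry in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def top(self, k: int) -> list[int]:
        """Gene ids of the top ``k`` ranks (clamped to the list length)."""
        return self.gene_ids[: max(0, k)]


def _retrieved_link_counts(corpus: Corpus, retrieved: Iterable[int]) -> dict[int, int]:
    """k_i: number of retrieved publications linked to each gene."""
    counts: dict[int, int] = {}
    for pmid in retrieved:
        for gene_id in corpus.genes_of_pub.get(pmid, ()):
            counts[gene_id] = counts.get(gene_id, 0) + 1
    return counts


def weighted_literature_score(
    corpus: Corpus, retrieved: Iterable[int]
) -> list[GeneScore]:
    """WLS_i = Σ_j∈retrieved f(i,j) / P_j for genes with ≥1 retrieved link."""
    totals: dict[int, float] = {}
    for pmid in retrieved:
        genes = corpus.genes_of_pub.get(pmid)
        if not genes:
            continue
        weight = 1.0 / len(genes)
        for gene_id in genes:
            totals[gene_id] = totals.get(gene_id, 0.0) + weight
    return [GeneScore(g, v, "wls") for g, v in sorted(totals.items())]


def publication_count_score(
    corpus: Corpus, retrieved: Iterable[int]
) -> list[GeneScore]:
    """Number of retrieved publications linked to each gene."""
    counts = _retrieved_link_counts(corpus, retrieved)
    return [GeneScore(g, float(k), "count") for g, k in sorted(counts.items())]


def tfidf_score(corpus: Corpus, retrieved: Iterable[int]) -> list[GeneScore]:
    """Modified TF-IDF: retrieved count times ln(n / L_i)."""
    if corpus.n_publications <= 0:
        raise ValidationError("corpus has no publications")
    counts = _retrieved_link_counts(corpus, retrieved)
    n = corpus.n_publications
    return [
        GeneScore(g, k * math.log(n / corpus.literature_count(g)), "tfidf")
        for g, k in sorted(counts.items())
    ]


def hypergeometric_score(corpus: Corpus, retrieved: Iterable[int]) -> list[GeneScore]:
    """BH-adjusted upper-tail hypergeometric enrichment p-values.

    For gene *i* with L_i total corpus publications, k_i of them among the K
    retrieved ones, the raw p-value is P(X >= k_i) for X hypergeometric with
    population N = n_publications, K successes and L_i draws.  Adjustment is
    Benjamini–Hochberg across all emitted genes.
    """
    retrieved = set(retrieved)
    if not retrieved:
        raise ValidationError("hypergeometric score requires >= 1 retrieved pmid")
    counts = _retrieved_link_counts(corpus, retrieved)
    genes = sorted(counts)
    n_total = corpus.n_publications
    n_successes = len(retrieved)
    raw = np.array(
        [
            hypergeom.sf(counts[g] - 1, n_total, n_successes, corpus.literature_count(g))
            for g in genes
        ]
    )
    # sf can land an ulp above 1 for k_i = 0-like corners; clamp into (0, 1]
    raw = np.clip(raw, np.finfo(float).tiny, 1.0)
    adjusted = bh_adjust(raw)
    return [GeneScore(g, float(p), "hypergeom") for g, p in zip(genes, adjusted)]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, capped at 1, in input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


_SCORERS = {
    "wls": weighted_literature_score,
    "count": publication_count_score,
    "tfidf": tfidf_score,
    "hypergeom": hypergeometric_score,
}


def score_genes(corpus: Corpus, retrieved: Iterable[int], method: str) -> list[GeneScore]:
    """Dispatch to one of the four scoring methods by name."""
    if method not in _SCORERS:
        raise ValidationError(f"unknown scoring method {method!r}; expected {METHODS}")
    return _SCORERS[method](corpus, set(retrieved))


def rank_genes(scores: Iterable[GeneScore]) -> RankedGeneList:
    """Sort scores into a 1-based ranking.

    Descending for wls/count/tfidf, ascending for hypergeom p-values; ties
    break by ascending gene_id, so the ordering is a deterministic function
    of the score set.
    """
    scores = list(scores)
    if not scores:
        return RankedGeneList(entries=(), method="")
    methods = {s.method for s in scores}
    if len(methods) > 1:
        raise ValidationError(f"mixed scoring methods in one ranking: {sorted(methods)}")
    method = scores[0].method
    sign = 1.0 if method in ASCENDING_METHODS else -1.0
    ordered = sorted(scores, key=lambda s: (sign * s.value, s.gene_id))
    return RankedGeneList(entries=tuple(ordered), method=method)
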