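"""Scoring methods: hand-computed values, conservation of the weighted
literature score, hypergeometric enumeration oracle, and BH adjustment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshprio.corpus import GeneLink, build_corpus
from meshprio.exceptions import ValidationError
from meshprio.scoring import (
    GeneScore,
    bh_adjust,
    hypergeometric_score,
    publication_count_score,
    rank_genes,
    score_genes,
    tfidf_score,
    weighted_literature_score,
)


def corpus_from(pub_genes: dict[int, set[int]]):
    links = {GeneLink(9606, g, p) for p, genes in pub_genes.items() for g in genes}
    return build_corpus(links, {})


class TestWeightedLiteratureScore:
    def test_inverse_gene_count_weighting(self):
        corpus = corpus_from({1: {10}, 2: {10, 11, 12, 13}})
        scores = {s.gene_id: s.value for s in weighted_literature_score(corpus, {1, 2})}
        assert scores[10] == pytest.approx(1.25)  # 1/1 + 1/4

    def test_equals_count_when_all_pubs_cite_one_gene(self):
        corpus = corpus_from({p: {p % 3 + 1} for p in range(1, 10)})
        retrieved = set(range(1, 10))
        wls = {s.gene_id: s.value for s in weighted_literature_score(corpus, retrieved)}
        cnt = {s.gene_id: s.value for s in publication_count_score(corpus, retrieved)}
        assert wls == cnt

    def test_gene_without_retrieved_link_absent(self):
        corpus = corpus_from({1: {10}, 2: {20}})
        scores = weighted_literature_score(corpus, {1})
        assert [s.gene_id for s in scores] == [10]

    def test_conservation_on_random_corpora(self):
        """Σ_i WLS_i equals the number of retrieved publications with at
        least one gene link: each publication hands out exactly one unit."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_pubs = int(rng.integers(2, 30))
            pub_genes = {
                p: set(map(int, rng.choice(40, size=rng.integers(1, 6), replace=False) + 1))
                for p in range(1, n_pubs + 1)
            }
            corpus = corpus_from(pub_genes)
            retrieved = {p for p in pub_genes if rng.random() < 0.6}
            total = sum(s.value for s in weighted_literature_score(corpus, retrieved))
            assert total == pytest.approx(len(retrieved), abs=1e-9)

    def test_wls_bounded_by_count_and_literature_size(self):
        rng = np.random.default_rng(5)
        pub_genes = {
            p: set(map(int, rng.choice(20, size=rng.integers(1, 5), replace=False) + 1))
            for p in range(1, 25)
        }
        corpus = corpus_from(pub_genes)
        retrieved = set(range(1, 15))
        wls = {s.gene_id: s.value for s in weighted_literature_score(corpus, retrieved)}
        cnt = {s.gene_id: s.value for s in publication_count_score(corpus, retrieved)}
        for g, v in wls.items():
            assert 0 <= v <= cnt[g] + 1e-12
            assert cnt[g] <= corpus.literature_count(g)


class TestPublicationCount:
    def test_simple_count(self):
        corpus = corpus_from({p: {10} if p <= 3 else {20} for p in range(1, 6)})
        scores = {s.gene_id: s.value for s in publication_count_score(corpus, set(range(1, 6)))}
        assert scores == {10: 3.0, 20: 2.0}

    def test_disjoint_retrieval_empty(self):
        corpus = corpus_from({1: {10}})
        assert publication_count_score(corpus, {99}) == []


class TestTfIdf:
    def test_hand_computed_value(self):
        # gene 1 in 10 of 100 pubs; all 10 retrieved -> 10 * ln(100/10)
        pub_genes = {p: {1} for p in range(1, 11)}
        pub_genes.update({p: {2} for p in range(11, 101)})
        corpus = corpus_from(pub_genes)
        scores = {s.gene_id: s.value for s in tfidf_score(corpus, set(range(1, 11)))}
        assert scores[1] == pytest.approx(10 * math.log(10), abs=1e-9)

    def test_ubiquitous_gene_scores_zero(self):
        corpus = corpus_from({p: {1} for p in range(1, 6)})
        scores = {s.gene_id: s.value for s in tfidf_score(corpus, {1, 2})}
        assert scores[1] == pytest.approx(0.0)


def hypergeom_upper_tail_oracle(n_pop, n_success, n_draws, k):
    """P(X >= k) by exhaustive enumeration of all C(n_pop, n_draws) draws."""
    population = range(n_pop)
    successes = set(range(n_success))
    hits = total = 0
    for draw in itertools.combinations(population, n_draws):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_fully_enriched_gene(self):
        # N=10, K=5 retrieved, L_i=5, k_i=5 -> p = 1/C(10,5) = 1/252
        pub_genes = {p: {1} for p in range(1, 6)}
        pub_genes.update({p: {2} for p in range(6, 11)})
        corpus = corpus_from(pub_genes)
        scores = hypergeometric_score(corpus, {1, 2, 3, 4, 5})
        (s,) = [x for x in scores if x.gene_id == 1]
        assert s.value == pytest.approx(1 / 252, rel=1e-9)

    def test_raw_p_matches_enumeration(self):
        """scipy's survival function agrees with brute-force draw enumeration
        for every population configuration up to N = 12."""
        from scipy.stats import hypergeom

        for n_pop in (5, 8, 12):
            for n_success in (1, 3, n_pop // 2):
                for n_draws in (1, 2, n_pop // 2):
                    for k in range(0, min(n_success, n_draws) + 1):
                        expected = hypergeom_upper_tail_oracle(
                            n_pop, n_success, n_draws, k
                        )
                        got = hypergeom.sf(k - 1, n_pop, n_success, n_draws)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_retrieval_rejected(self):
        corpus = corpus_from({1: {1}})
        with pytest.raises(ValidationError):
            hypergeometric_score(corpus, set())


class TestBHAdjust:
    @pytest.mark.parametrize(
        ("raw", "expected"),
        [
            ([0.05], [0.05]),
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ],
    )
    def test_step_up_rule(self, raw, expected):
        assert bh_adjust(raw) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(
            st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=15
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_equivariance_and_bounds(self, pvals, rnd):
        adjusted = bh_adjust(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)
        assert np.all(adjusted <= 1.0 + 1e-15)
        order = list(range(len(pvals)))
        rnd.shuffle(order)
        shuffled = bh_adjust([pvals[i] for i in order])
        assert shuffled == pytest.approx([adjusted[i] for i in order], abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust(bad)


class TestRankGenes:
    def test_descending_with_gene_id_tie_break(self):
        scores = [GeneScore(2, 1.0, "wls"), GeneScore(1, 1.0, "wls"), GeneScore(3, 2.0, "wls")]
        assert rank_genes(scores).gene_ids == [3, 1, 2]

    def test_hypergeom_sorts_ascending(self):
        scores = [GeneScore(1, 0.5, "hypergeom"), GeneScore(2, 0.01, "hypergeom")]
        assert rank_genes(scores).gene_ids == [2, 1]

    def test_empty_input(self):
        assert len(rank_genes([])) == 0

    def test_mixed_methods_rejected(self):
        with pytest.raises(ValidationError):
            rank_genes([GeneScore(1, 1.0, "wls"), GeneScore(2, 1.0, "count")])

    def test_identical_rankings_when_every_pub_cites_one_gene(self):
        corpus = corpus_from({p: {(p * 7) % 5 + 1} for p in range(1, 20)})
        retrieved = set(range(1, 20))
        orders = {
            method: rank_genes(score_genes(corpus, retrieved, method)).gene_ids
            for method in ("wls", "count", "tfidf")
        }
        assert orders["wls"] == orders["count"] == orders["tfidf"]
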