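"""Shared fixtures: tiny hand-checkable corpora and a small synthetic corpus."""

from __future__ import annotations

import numpy as np
import pytest

from meshprio.corpus import GeneLink, ValidationSet, build_corpus
from meshprio.synthetic import GeneratorParams, generate_corpus


@pytest.fixture
def toy_corpus():
    """Three publications: P1{Pain,Hyperalgesia}, P2{Pain}, P3{Hyperalgesia},
    each carrying one gene link so every publication is in the corpus."""
    links = {
        GeneLink(9606, 11, 1),
        GeneLink(9606, 12, 2),
        GeneLink(9606, 13, 3),
    }
    annotations = {
        1: {"Pain", "Hyperalgesia"},
        2: {"Pain"},
        3: {"Hyperalgesia"},
    }
    return build_corpus(links, annotations, restrict_to_linked=True)


def random_corpus(rng: np.random.Generator, n_pubs: int = 20, n_genes: int = 8,
                  n_terms: int = 5):
    """A small random corpus for property tests: every publication carries at
    least one gene link; term annotation is Bernoulli per (pub, term)."""
    links = set()
    annotations: dict[int, set[str]] = {}
    terms = [f"T{i}" for i in range(n_terms)]
    for pmid in range(1, n_pubs + 1):
        cited = rng.choice(n_genes, size=rng.integers(1, 4), replace=False) + 1
        for g in cited:
            links.add(GeneLink(9606, int(g), pmid))
        carried = {t for t in terms if rng.random() < 0.4}
        if carried:
            annotations[pmid] = carried
    return build_corpus(links, annotations, restrict_to_linked=True)


@pytest.fixture(scope="session")
def small_synthetic(tmp_path_factory):
    """One small generated corpus (400 pubs) reused across tests."""
    params = GeneratorParams(n_genes=120, n_disease_genes=15, n_pubs=400,
                             omics_min_genes=20, rng_seed=7)
    out = tmp_path_factory.mktemp("synthetic")
    return params, generate_corpus(params, out)


@pytest.fixture
def validation_set():
    return ValidationSet(frozenset({11, 13}), label="toy")
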