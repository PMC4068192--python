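"""Synthetic literature corpora with planted disease structure.

The generator emits the three input dialects the pipeline consumes
(gene2pubmed links, per-publication MeSH annotations, homologene ortholog
groups) plus a truth record, so every stage runs and can be validated
offline.  The planted structure mirrors the statistical assumptions the
method exploits:

* a fraction of publications are *disease* papers: they carry the seed
  descriptor and similarity-enriched related descriptors at elevated
  probability, and cite planted disease genes at ``link_enrichment``-fold
  odds;
* a fraction are *omics* papers (microarray/sequencing style): they cite
  many genes (``>= omics_min_genes``) drawn uniformly, and carry descriptors
  only at background rates — the noise source the weighted literature score
  is designed to down-weight;
* the remainder are *background* papers with few, uniformly drawn genes.

Each conceptual gene g in 1..n_genes has one record per species (human id g,
mouse id n_genes+g, rat id 2·n_genes+g) grouped in the homologene table, and
every citation picks a species at random, so ortholog collapse is exercised
end to end and recovers the conceptual id (the human representative).

Identical parameters (including ``rng_seed``) produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import corpus as corpus_io
from . import ortholog as ortholog_io
from .corpus import GeneLink, ValidationSet
from .exceptions import ParseError, ValidationError
from .ortholog import OrthologGroup

__all__ = [
    "DEFAULT_RELATED_TERMS",
    "GeneratorParams",
    "Truth",
    "SyntheticCorpus",
    "generate_corpus",
    "generate_validation_sets",
    "read_truth",
    "termset_recovery_params",
]

#: descriptor -> (probability in disease pubs, probability in other pubs).
#: The first five are planted enriching descriptors (disease prob well above
#: background); the rest are distractors — either rare everywhere or frequent
#: everywhere (tissue/method/reagent-style terms with no disease specificity).
DEFAULT_RELATED_TERMS: dict[str, tuple[float, float]] = {
    "Pain Measurement": (0.17, 0.0),
    "Nociceptors": (0.16, 0.0),
    "Pain Threshold": (0.15, 0.0),
    "Hyperalgesia": (0.14, 0.0),
    "Analgesics": (0.13, 0.0),
    "Physical Stimulation": (0.05, 0.05),
    "Injections, Spinal": (0.05, 0.05),
    "Formaldehyde": (0.04, 0.05),
    "Rats": (0.20, 0.20),
    "Disease Models, Animal": (0.15, 0.15),
}

_SPECIES_OFFSETS = {9606: 0, 10090: 1, 10116: 2}


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for one synthetic corpus.

    Defaults describe a small literature of 2000 publications over 500
    conceptual genes, 50 of them disease genes cited at 5-fold odds in
    disease papers; 20% of papers are disease papers, 5% are many-gene omics
    papers.  The seed descriptor marks 40% of disease papers, 20% of omics
    papers (a fifth of the screens are disease-focused — the very
    publications whose many-gene citation lists the weighted literature
    score exists to down-weight) and 2% of background papers.  Enriching
    related descriptors behave as exclusive topical facets of the disease
    literature; distractor descriptors attach independently everywhere.
    """

    n_genes: int = 500
    n_disease_genes: int = 50
    n_pubs: int = 2000
    disease_pub_fraction: float = 0.2
    seed_term: str = "Pain"
    seed_term_prob: float = 0.4
    background_term_prob: float = 0.02
    omics_seed_term_prob: float = 0.2
    related_term_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RELATED_TERMS)
    )
    genes_per_pub_p: float = 0.5  # geometric success prob, support 1..max
    genes_per_pub_max: int = 10
    omics_fraction: float = 0.05
    omics_min_genes: int = 50
    link_enrichment: float = 5.0
    species_mix: Mapping[int, float] = field(
        default_factory=lambda: {9606: 0.5, 10090: 0.35, 10116: 0.15}
    )
    rng_seed: int = 42

    def validate(self) -> None:
        if not 0 < self.n_disease_genes <= self.n_genes:
            raise ValidationError("need 0 < n_disease_genes <= n_genes")
        if self.n_pubs < 1:
            raise ValidationError("n_pubs must be >= 1")
        probs = [
            self.disease_pub_fraction,
            self.seed_term_prob,
            self.background_term_prob,
            self.omics_seed_term_prob,
            self.omics_fraction,
        ]
        for p_d, p_b in self.related_term_probs.values():
            probs.extend([p_d, p_b])
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if not 0 < self.disease_pub_fraction < 1:
            raise ValidationError("disease_pub_fraction must lie in (0, 1)")
        if self.omics_fraction + self.disease_pub_fraction > 1:
            raise ValidationError(
                "omics_fraction + disease_pub_fraction must not exceed 1"
            )
        if not 0 < self.omics_min_genes <= self.n_genes:
            raise ValidationError("need 0 < omics_min_genes <= n_genes")
        if not 0 < self.genes_per_pub_max <= self.n_genes:
            raise ValidationError("need 0 < genes_per_pub_max <= n_genes")
        if not 0 < self.genes_per_pub_p <= 1:
            raise ValidationError("genes_per_pub_p must lie in (0, 1]")
        if self.link_enrichment < 1:
            raise ValidationError("link_enrichment must be >= 1")
        facet_total = sum(
            p_d for p_d, p_b in self.related_term_probs.values() if p_d > p_b
        )
        if facet_total > 1:
            raise ValidationError(
                "enriching-term disease probabilities (the facet slices) must "
                f"sum to <= 1, got {facet_total:.3f}"
            )
        unknown = set(self.species_mix) - set(_SPECIES_OFFSETS)
        if unknown:
            raise ValidationError(f"unsupported species in mix: {sorted(unknown)}")
        if not self.species_mix or any(w <= 0 for w in self.species_mix.values()):
            raise ValidationError("species_mix weights must be positive")

    @property
    def enriching_terms(self) -> list[str]:
        """Planted descriptors whose disease probability exceeds background."""
        return [t for t, (p_d, p_b) in self.related_term_probs.items() if p_d > p_b]


def termset_recovery_params(rng_seed: int = 0) -> GeneratorParams:
    """Study conditions for the term-set recovery experiment.

    A larger gene universe (2000 genes, 150 disease genes, 4000 publications)
    than the scoring-comparison default, so that retrieval cannot saturate
    the candidate list and the recall-at-k peak over nested term sets is
    resolvable.  Seed coverage is moderate (30% of disease papers) to leave
    headroom for the planted related descriptors, and omics contamination of
    the seed query is light (5%).
    """
    return GeneratorParams(
        n_genes=2000,
        n_disease_genes=150,
        n_pubs=4000,
        disease_pub_fraction=0.2,
        seed_term_prob=0.3,
        background_term_prob=0.02,
        omics_seed_term_prob=0.05,
        rng_seed=rng_seed,
    )


@dataclass(frozen=True)
class Truth:
    """Ground truth of one generated corpus (post-collapse identifiers)."""

    disease_genes: frozenset[int]
    all_genes: frozenset[int]
    enriching_terms: tuple[str, ...]
    pub_categories: dict[int, str]  # pmid -> disease | omics | background
    seed_term: str

    @property
    def background_genes(self) -> frozenset[int]:
        return self.all_genes - self.disease_genes


@dataclass(frozen=True)
class SyntheticCorpus:
    gene2pubmed_path: Path
    annotations_path: Path
    homologene_path: Path
    truth_path: Path
    truth: Truth


def _pub_categories(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    n_disease = round(params.disease_pub_fraction * params.n_pubs)
    n_omics = round(params.omics_fraction * params.n_pubs)
    cats = np.array(
        ["disease"] * n_disease
        + ["omics"] * n_omics
        + ["background"] * (params.n_pubs - n_disease - n_omics)
    )
    rng.shuffle(cats)
    return cats


def generate_corpus(
    params: GeneratorParams, out_dir: Path | str
) -> SyntheticCorpus:
    """Generate one corpus and write its four files under ``out_dir``."""
    params.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.rng_seed)

    n_genes = params.n_genes
    # random ids so rank tie-breaking (ascending gene_id) cannot favor them
    disease_idx = np.sort(
        rng.choice(n_genes, size=params.n_disease_genes, replace=False)
    )
    disease_genes = frozenset(int(g) + 1 for g in disease_idx)
    categories = _pub_categories(params, rng)

    taxa = sorted(params.species_mix)
    tax_weights = np.array([params.species_mix[t] for t in taxa], dtype=float)
    tax_weights /= tax_weights.sum()

    disease_weights = np.ones(n_genes)
    disease_weights[disease_idx] = params.link_enrichment
    disease_weights /= disease_weights.sum()

    # Enriching descriptors (disease prob above background) act as exclusive
    # topical facets of the disease literature: a disease paper is
    # predominantly about at most one of them.  Distractor descriptors attach
    # independently in every category.
    facet_terms = sorted(
        t for t, (p_d, p_b) in params.related_term_probs.items() if p_d > p_b
    )
    facet_probs = np.array(
        [params.related_term_probs[t][0] for t in facet_terms]
        + [1.0 - sum(params.related_term_probs[t][0] for t in facet_terms)]
    )
    distractor_terms = sorted(
        t for t in params.related_term_probs if t not in facet_terms
    )

    links: set[GeneLink] = set()
    annotations: dict[int, set[str]] = {}
    for pmid0, category in enumerate(categories):
        pmid = pmid0 + 1
        if category == "omics":
            size = params.omics_min_genes + int(rng.geometric(0.2)) - 1
            size = min(size, n_genes)
            cited = rng.choice(n_genes, size=size, replace=False) + 1
        else:
            size = min(int(rng.geometric(params.genes_per_pub_p)), params.genes_per_pub_max)
            if category == "disease":
                cited = rng.choice(n_genes, size=size, replace=False, p=disease_weights) + 1
            else:
                cited = rng.choice(n_genes, size=size, replace=False) + 1
        for gene in np.sort(cited):
            tax = taxa[rng.choice(len(taxa), p=tax_weights)]
            raw_id = _SPECIES_OFFSETS[tax] * n_genes + int(gene)
            links.add(GeneLink(tax, raw_id, pmid))

        terms: set[str] = set()
        is_disease = category == "disease"
        if category == "omics":
            p_seed = params.omics_seed_term_prob
        elif is_disease:
            p_seed = params.seed_term_prob
        else:
            p_seed = params.background_term_prob
        if rng.random() < p_seed:
            terms.add(params.seed_term)
        if is_disease and facet_terms:
            facet = int(rng.choice(len(facet_terms) + 1, p=facet_probs))
            if facet < len(facet_terms):
                terms.add(facet_terms[facet])
        elif facet_terms:
            for term in facet_terms:
                p_b = params.related_term_probs[term][1]
                if p_b > 0 and rng.random() < p_b:
                    terms.add(term)
        for term in distractor_terms:
            p_d, p_b = params.related_term_probs[term]
            if rng.random() < (p_d if is_disease else p_b):
                terms.add(term)
        if terms:
            annotations[pmid] = terms

    groups = [
        OrthologGroup(
            group_id=g,
            members=frozenset(
                (tax, _SPECIES_OFFSETS[tax] * n_genes + g) for tax in _SPECIES_OFFSETS
            ),
            representative=g,
        )
        for g in range(1, n_genes + 1)
    ]

    truth = Truth(
        disease_genes=disease_genes,
        all_genes=frozenset(range(1, n_genes + 1)),
        enriching_terms=tuple(params.enriching_terms),
        pub_categories={i + 1: c for i, c in enumerate(categories)},
        seed_term=params.seed_term,
    )

    gene2pubmed_path = out_dir / "gene2pubmed.tsv"
    annotations_path = out_dir / "annotations.tsv"
    homologene_path = out_dir / "homologene.data"
    truth_path = out_dir / "truth.tsv"
    corpus_io.write_gene2pubmed(links, gene2pubmed_path)
    corpus_io.write_mesh_annotations(annotations, annotations_path)
    ortholog_io.write_homologene(groups, homologene_path)
    _write_truth(truth, truth_path)

    return SyntheticCorpus(
        gene2pubmed_path=gene2pubmed_path,
        annotations_path=annotations_path,
        homologene_path=homologene_path,
        truth_path=truth_path,
        truth=truth,
    )


def _write_truth(truth: Truth, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#kind\tkey\tvalue\n")
        handle.write(f"seed_term\t{truth.seed_term}\t-\n")
        for term in truth.enriching_terms:
            handle.write(f"enriching_term\t{term}\t-\n")
        for gene in sorted(truth.all_genes):
            kind = "disease_gene" if gene in truth.disease_genes else "background_gene"
            handle.write(f"{kind}\t{gene}\t-\n")
        for pmid in sorted(truth.pub_categories):
            handle.write(f"pub_category\t{pmid}\t{truth.pub_categories[pmid]}\n")


def read_truth(path: Path | str) -> Truth:
    """Reload a truth sidecar written by :func:`generate_corpus`."""
    disease: set[int] = set()
    background: set[int] = set()
    enriching: list[str] = []
    pub_categories: dict[int, str] = {}
    seed_term = ""
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            kind, key, value = parts
            if kind == "seed_term":
                seed_term = key
            elif kind == "enriching_term":
                enriching.append(key)
            elif kind == "disease_gene":
                disease.add(int(key))
            elif kind == "background_gene":
                background.add(int(key))
            elif kind == "pub_category":
                pub_categories[int(key)] = value
            else:
                raise ParseError(f"{path}:{lineno}: unknown record kind {kind!r}")
    return Truth(
        disease_genes=frozenset(disease),
        all_genes=frozenset(disease | background),
        enriching_terms=tuple(enriching),
        pub_categories=pub_categories,
        seed_term=seed_term,
    )


def generate_validation_sets(
    truth: Truth,
    recall_ceiling: float = 0.8,
    noise: float = 0.1,
    rng_seed: int = 0,
) -> tuple[ValidationSet, ValidationSet]:
    """Draw two independent validation rosters from the planted truth.

    Each set keeps a ``recall_ceiling`` fraction of the planted disease genes
    and adds background genes so that a ``noise`` fraction of its members are
    off-target.  The two sets use independent child seed streams, so set 2 is
    a genuinely different draw.
    """
    if not 0 < recall_ceiling <= 1:
        raise ValidationError("recall_ceiling must lie in (0, 1]")
    if not 0 <= noise < 1:
        raise ValidationError("noise must lie in [0, 1)")
    children = np.random.SeedSequence(rng_seed).spawn(2)
    planted = np.array(sorted(truth.disease_genes))
    pool = np.array(sorted(truth.background_genes))
    sets = []
    for label, child in zip(("set1", "set2"), children):
        rng = np.random.default_rng(child)
        n_keep = max(1, round(recall_ceiling * planted.size))
        kept = rng.choice(planted, size=n_keep, replace=False)
        n_noise = round(noise * n_keep / (1 - noise)) if noise > 0 else 0
        n_noise = min(n_noise, pool.size)
        noisy = rng.choice(pool, size=n_noise, replace=False) if n_noise else []
        sets.append(
            ValidationSet(frozenset(int(g) for g in (*kept, *noisy)), label=label)
        )
    return sets[0], sets[1]
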