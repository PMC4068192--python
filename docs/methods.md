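# Methods

## Corpus model

The corpus is two bipartite graphs over a shared publication axis:
publication↔gene from a gene2pubmed-style table of curated links, and
publication↔MeSH descriptor from a flat two-column annotation table. All
downstream quantities are set-size queries on these indexes: `L_i` (a gene's
total linked publications), `P_j` (a publication's linked genes, whose
membership is the indicator `f(i,j)`), and descriptor publication sets.

By default the term index is restricted to gene-linked publications
(`restrict_to_linked=True`), so descriptor co-occurrence is measured over the
same literature the genes come from. Annotation input is a flat
`pmid<TAB>descriptor` TSV rather than MEDLINE XML, keeping the artifact
self-contained; descriptors are compared by exact, case-sensitive string
equality, the flat-model equivalent of a no-explosion (`NoExp`) MeSH query.

Cross-species redundancy is removed before indexing: HomoloGene-style groups
map every member to one representative, chosen as the human (tax 9606)
member's gene id when present and otherwise the smallest member id — the
source data name no canonical member, so a deterministic rule is required.
Genes in no group keep their own id (singleton semantics); discarding them
instead would silently drop species-specific candidates.

## Descriptor similarity and term-set selection

Five co-occurrence measures are supported (cosine, Dice, Jaccard, Simpson,
PMI). Numerical conventions:

* PMI (and TF-IDF below) uses the natural logarithm; changing base rescales
  but never reorders.
* The corpus size N in PMI probabilities is the number of publications
  carrying at least one descriptor when the corpus is restricted, and the
  number of publications known to either index otherwise (this keeps every
  count ≤ N). Rankings are invariant to this choice: N shifts every PMI by
  the same constant and the bounded measures ignore it.
* Descriptors that never co-occur with the seed are excluded from rankings
  rather than scored −∞: they can never improve a term set and PMI is
  undefined for them. The seed itself is always rank 1.
* Ties break by ascending lexicographic descriptor, making rankings a pure
  function of the corpus.

Nested candidate sets grow one descriptor at a time in similarity order.
Each set retrieves the union of exact-match publication sets; gathered genes
are ranked (by the weighted literature score unless configured otherwise)
and scored by recall-at-k against the first validation gene set, with k
fixed at the seed-only baseline's gene count so that shorter and longer
lists are compared at the same depth. The arg-max set wins; ties go to the
smaller set (cheaper queries, no evidence the extra term helps). A rank
cutoff beyond the list length is clamped with a warning.

## Prioritization scores

* `wls` — `WLS_i = Σ_{j∈retrieved} f(i,j)/P_j`. Each gene-linked retrieved
  publication distributes exactly one unit of evidence among its genes, so
  `Σ_i WLS_i` equals the number of gene-linked retrieved publications — a
  conservation law the tests exploit.
* `count` — retrieved-publication count.
* `tfidf` — `count_i · ln(n/L_i)` with n the corpus size and `L_i` the
  gene's global literature count (a retrieval-restricted `L_i` would make
  the IDF factor depend on the query; the global form measures how specific
  the gene's literature is overall).
* `hypergeom` — upper-tail (enrichment) hypergeometric p-value of observing
  `k_i` of the gene's `L_i` publications among the K retrieved ones in a
  corpus of N, Benjamini–Hochberg adjusted across the emitted genes.
  The upper tail is the only direction meaningful for prioritization.

Score sums run over the retrieved publication set while `P_j`, `L_i` and n
are global corpus quantities; a fully global sum would make scores identical
for every disease query. Genes with no retrieved link are omitted rather
than scored zero — gathering precedes scoring. Rankings sort descending
(ascending for p-values) with ties broken by ascending gene id, so a ranking
is a deterministic function of the score set.

## Evaluation

Cumulative curves at every rank n: `R(n) = T_n/C`, `P(n) = T_n/E_n`,
`F(n) = 2PR/(P+R)` (0 when both are 0), with `E_n = n` for the package's own
lists — the extra generality of `E_n` exists for scoring external tools'
lists, which this package does not do. Maximum F reports the smallest rank
attaining the maximum.

Two methods' recall curves are compared with a one-sided paired Wilcoxon
signed-rank test (alternative: first curve exceeds the second), pairing by
rank index over the shared range after truncating to the shorter curve.
Zero differences are dropped. With ≤ 20 nonzero pairs the null is computed
exactly by dynamic programming over the (possibly tied, half-integer) rank
multiset — equivalent to enumerating all 2^m sign assignments; beyond that a
normal approximation with tie-corrected variance and no continuity
correction is used. All-zero differences raise a degenerate-input error
rather than returning p = 1. The pairing unit and sidedness are this
package's construction choices for curve comparison.

## Synthetic corpus generator

The generator emulates the statistical structure the method exploits, not
MEDLINE realism. Publications fall into three categories with exact counts
(rounded fractions of `n_pubs`):

* **disease** (`disease_pub_fraction`, default 0.2) — cite
  `link_enrichment`-fold (default 5) enriched disease genes, carry the seed
  descriptor with probability `seed_term_prob` (0.4) and at most one
  *enriching facet* descriptor drawn categorically from the planted related
  terms (a disease paper is predominantly about one aspect: measurement,
  nociceptors, …). The facet construction — rather than independent
  Bernoulli terms — gives each planted descriptor a near-constant slice of
  exclusive coverage, so each one contributes comparable retrieval gain and
  the recall peak over nested sets is resolvable at small corpus sizes.
* **omics** (`omics_fraction`, default 0.05) — cite at least
  `omics_min_genes` (default 50) uniformly drawn genes (50 + a geometric
  tail), and carry the seed descriptor with probability
  `omics_seed_term_prob` (default 0.2): a fifth of the screens are
  disease-focused, which is exactly the contamination the weighted
  literature score exists to down-weight. Without seed-retrievable omics
  papers the count-vs-WLS comparison would be vacuous.
* **background** (the rest) — uniform genes, seed descriptor at
  `background_term_prob` (0.02).

Distractor descriptors ("Rats", "Formaldehyde", …) attach independently with
equal probability everywhere — frequent-but-nonspecific terms that mirror
the tissue/method/reagent headings which degrade real retrieval. Non-omics
gene counts are truncated-geometric on 1..10 (p = 0.5). Disease-gene ids are
drawn at random so the deterministic ascending-id tie-break cannot favor
them. Every conceptual gene has one record per species (human id g, mouse
n+g, rat 2n+g) grouped in the homologene output, and each citation picks a
species from `species_mix`, so ortholog collapse is exercised end to end.

Identical parameters and seed give byte-identical files. Validation sets are
drawn from independent child seed streams: each keeps a `recall_ceiling`
fraction of the planted genes and adds background genes so a `noise`
fraction of members is off-target.

Two named study conditions are used:

* the **scoring comparison** uses the defaults (500 genes, 50 disease genes,
  2000 publications) — small enough to run in seconds while omics
  contamination measurably separates the weighted score from the raw count;
* **term-set recovery** (`termset_recovery_params`) uses 2000 genes,
  150 disease genes, 4000 publications, moderate seed coverage
  (`seed_term_prob` 0.3) and light omics contamination
  (`omics_seed_term_prob` 0.05). In the small scoring corpus, retrieved
  omics papers cite a tenth of the whole gene universe and the baseline
  gathers nearly every gene, so recall-at-k cannot resolve a peak; the
  larger universe restores the headroom the selection experiment needs.

What passing tests on these corpora show — and what they do not: the
pipeline recovers planted structure under the generator's independence
assumptions (no citation-network correlation, no descriptor vocabulary
structure, no time axis, symmetric species usage). Performance numbers on
synthetic corpora say nothing quantitative about real MEDLINE-scale
corpora, where validation sets are curated externally and descriptor usage
is far richer.

## Numerical and degenerate-input conventions

* Similarity with a zero denominator (a descriptor on zero publications)
  and PMI with zero co-occurrence raise an undefined-similarity error;
  disjoint descriptor pairs with nonzero margins score 0 on the bounded
  measures.
* Hypergeometric survival probabilities are clamped into (0, 1] before BH
  adjustment (floating corner cases an ulp above 1).
* BH inputs outside (0, 1] are rejected rather than silently clipped.
* An empty validation set, an empty ranked list, an empty candidate-set
  list, and a baseline query that gathers zero genes are all errors, not
  silent empties.
* Weighted-score conservation holds to 1e-9 absolute (floating addition
  order), and the enumeration oracles agree to 1e-12.

## Known limitations

* Exact descriptor matching means no MeSH tree explosion; queries behave
  like `[MeSH:NoExp]` only.
* The Wilcoxon pairing unit (rank index) treats per-rank recall differences
  as exchangeable, which is an approximation — adjacent ranks are highly
  dependent.
* The generator's facet model caps enriching-descriptor co-occurrence (two
  planted descriptors never share a disease paper), which slightly deflates
  their mutual similarity relative to real MeSH co-assignment.
* Ortholog collapse resolves ties deterministically but arbitrarily when a
  group has several members in the representative species' table entries;
  paralog disambiguation is out of scope.
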