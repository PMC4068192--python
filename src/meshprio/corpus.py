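"""Readers, writers and the indexed corpus of gene–publication links and
per-publication MeSH annotations.

The corpus is a pair of bipartite graphs sharing the publication axis:
publications ↔ genes (from a gene2pubmed-style table of curated links) and
publications ↔ MeSH descriptors (from a flat two-column annotation table).
Both directions are kept as explicit transposed indexes because every
downstream quantity — per-publication gene counts ``P_j``, per-gene literature
counts ``L_i``, descriptor co-occurrence counts — is a set-size query on one
of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .exceptions import ParseError, ValidationError

__all__ = [
    "GeneLink",
    "Corpus",
    "ValidationSet",
    "read_gene2pubmed",
    "write_gene2pubmed",
    "read_mesh_annotations",
    "write_mesh_annotations",
    "read_gene_set",
    "write_gene_set",
    "build_corpus",
]


@dataclass(frozen=True, order=True)
class GeneLink:
    """One curated gene–publication association.

    Attributes
    ----------
    tax_id : int
        NCBI taxonomy identifier of the species the gene record belongs to.
    gene_id : int
        NCBI Gene identifier.
    pmid : int
        PubMed identifier of the linked publication.
    """

    tax_id: int
    gene_id: int
    pmid: int

    def __post_init__(self) -> None:
        for name in ("tax_id", "gene_id", "pmid"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value <= 0:
                raise ValidationError(
                    f"GeneLink.{name} must be a positive integer, got {value!r}"
                )


@dataclass(frozen=True)
class ValidationSet:
    """A reference roster of disease genes used for recall/precision.

    ``genes`` holds post-ortholog-collapse identifiers; its size is the ``C``
    in recall ``R(n) = T_n / C``.
    """

    genes: frozenset[int]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"validation set {self.label!r} is empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: int) -> bool:
        return gene_id in self.genes


@dataclass
class Corpus:
    """Indexed bipartite structures publication↔gene and publication↔term.

    ``pubs_of_gene[i]`` gives the publication set of gene *i* (``L_i`` is its
    size); ``genes_of_pub[j]`` gives the gene set of publication *j* (``P_j``
    is its size, and membership is the indicator ``f(i, j)``).
    ``n_publications`` is the number of distinct publications carrying at
    least one gene link.  ``restricted`` records whether the term index was
    limited to gene-linked publications when the corpus was built.
    """

    pubs_of_gene: dict[int, set[int]]
    genes_of_pub: dict[int, set[int]]
    pubs_of_term: dict[str, set[int]]
    terms_of_pub: dict[int, set[str]]
    n_publications: int
    restricted: bool = True

    def gene_count(self, pmid: int) -> int:
        """P_j: number of genes associated with publication ``pmid``."""
        return len(self.genes_of_pub.get(pmid, ()))

    def literature_count(self, gene_id: int) -> int:
        """L_i: number of corpus publications linked to ``gene_id``."""
        return len(self.pubs_of_gene.get(gene_id, ()))

    @property
    def n_annotated(self) -> int:
        """Number of publications carrying at least one MeSH descriptor."""
        return len(self.terms_of_pub)


def _data_lines(path: Path | str) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_gene2pubmed(path: Path | str) -> set[GeneLink]:
    """Parse a gene2pubmed-style TSV into a duplicate-free set of links.

    The dialect is three tab-separated integer columns
    (tax_id, GeneID, PubMed_ID); lines starting with ``#`` are headers.
    """
    links: set[GeneLink] = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        try:
            tax_id, gene_id, pmid = (int(p) for p in parts)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer field in {line!r}") from exc
        links.add(GeneLink(tax_id, gene_id, pmid))
    return links


def write_gene2pubmed(links: Iterable[GeneLink], path: Path | str) -> None:
    """Serialize links in the gene2pubmed dialect (sorted, deterministic)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#tax_id\tGeneID\tPubMed_ID\n")
        for link in sorted(set(links)):
            handle.write(f"{link.tax_id}\t{link.gene_id}\t{link.pmid}\n")


def read_mesh_annotations(path: Path | str) -> dict[int, set[str]]:
    """Parse a flat ``pmid<TAB>descriptor`` table into pmid → descriptor set.

    Descriptor strings are stripped of surrounding whitespace and compared
    case-sensitively (MeSH descriptors are a controlled vocabulary).
    """
    annotations: dict[int, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        try:
            pmid = int(parts[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer pmid {parts[0]!r}") from exc
        descriptor = parts[1].strip()
        if not descriptor:
            raise ParseError(f"{path}:{lineno}: empty descriptor")
        annotations.setdefault(pmid, set()).add(descriptor)
    return annotations


def write_mesh_annotations(
    annotations: Mapping[int, Iterable[str]], path: Path | str
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#pmid\tdescriptor\n")
        for pmid in sorted(annotations):
            for descriptor in sorted(annotations[pmid]):
                handle.write(f"{pmid}\t{descriptor}\n")


def read_gene_set(path: Path | str, label: str = "") -> ValidationSet:
    """Read a plain gene roster (one integer gene_id per line)."""
    genes: set[int] = set()
    for lineno, line in _data_lines(path):
        token = line.strip()
        try:
            genes.add(int(token))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer gene id {token!r}") from exc
    if not genes:
        raise ValidationError(f"{path}: gene set {label!r} is empty")
    return ValidationSet(frozenset(genes), label=label or str(path))


def write_gene_set(genes: Iterable[int], path: Path | str, label: str = "") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        if label:
            handle.write(f"# {label}\n")
        for gene_id in sorted(set(genes)):
            handle.write(f"{gene_id}\n")


def build_corpus(
    links: Iterable[GeneLink],
    annotations: Mapping[int, Iterable[str]] | None = None,
    restrict_to_linked: bool = True,
) -> Corpus:
    """Assemble the indexed corpus from links and annotations.

    When ``restrict_to_linked`` (the default), annotated publications with no
    gene link are dropped from the term index, so descriptor co-occurrence is
    measured only over the gene-linked literature.
    """
    links = set(links)
    if not links:
        raise ValidationError("cannot build a corpus from zero gene links")
    annotations = annotations or {}

    pubs_of_gene: dict[int, set[int]] = {}
    genes_of_pub: dict[int, set[int]] = {}
    for link in links:
        pubs_of_gene.setdefault(link.gene_id, set()).add(link.pmid)
        genes_of_pub.setdefault(link.pmid, set()).add(link.gene_id)

    pubs_of_term: dict[str, set[int]] = {}
    terms_of_pub: dict[int, set[str]] = {}
    for pmid, descriptors in annotations.items():
        if restrict_to_linked and pmid not in genes_of_pub:
            continue
        for descriptor in descriptors:
            descriptor = descriptor.strip()
            if not descriptor:
                continue
            pubs_of_term.setdefault(descriptor, set()).add(pmid)
            terms_of_pub.setdefault(pmid, set()).add(descriptor)

    return Corpus(
        pubs_of_gene=pubs_of_gene,
        genes_of_pub=genes_of_pub,
        pubs_of_term=pubs_of_term,
        terms_of_pub=terms_of_pub,
        n_publications=len(genes_of_pub),
        restricted=restrict_to_linked,
    )
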