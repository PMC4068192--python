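"""Cross-species gene unification via HomoloGene-style ortholog groups.

Pain and neurodegeneration literature mixes human, mouse and rat gene records
for what is biologically one gene; before ranking, links are collapsed so each
ortholog group contributes a single candidate.  The representative identifier
is the human member's gene_id when the group has one, otherwise the smallest
gene_id in the group (a deterministic rule — the underlying data name no
canonical member).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .corpus import GeneLink
from .exceptions import DataError, ParseError

HUMAN_TAX_ID = 9606
DEFAULT_SPECIES: frozenset[int] = frozenset({9606, 10090, 10116})  # human, mouse, rat

__all__ = [
    "OrthologGroup",
    "read_homologene",
    "write_homologene",
    "collapse",
    "DEFAULT_SPECIES",
    "HUMAN_TAX_ID",
]


@dataclass(frozen=True)
class OrthologGroup:
    group_id: int
    members: frozenset[tuple[int, int]]  # (tax_id, gene_id) pairs
    representative: int

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"ortholog group {self.group_id} has no members")
        if self.representative not in {g for _, g in self.members}:
            raise DataError(
                f"group {self.group_id}: representative {self.representative} "
                "is not a member gene"
            )


def _choose_representative(members: frozenset[tuple[int, int]]) -> int:
    human = sorted(g for tax, g in members if tax == HUMAN_TAX_ID)
    if human:
        return human[0]
    return min(g for _, g in members)


def read_homologene(
    path: Path | str, species: Iterable[int] = DEFAULT_SPECIES
) -> list[OrthologGroup]:
    """Parse a homologene.data-style TSV (6 columns, no header).

    Columns: group id, tax id, gene id, gene symbol, protein gi, protein
    accession.  Rows whose tax id is outside ``species`` are dropped; groups
    left with no member are omitted.  A gene appearing in two groups is a
    data error.
    """
    species = frozenset(species)
    raw_groups: dict[int, set[tuple[int, int]]] = {}
    seen: dict[tuple[int, int], int] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                group_id, tax_id, gene_id = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if tax_id not in species:
                continue
            key = (tax_id, gene_id)
            if key in seen and seen[key] != group_id:
                raise DataError(
                    f"gene {gene_id} (tax {tax_id}) appears in groups "
                    f"{seen[key]} and {group_id}"
                )
            seen[key] = group_id
            raw_groups.setdefault(group_id, set()).add(key)
    return [
        OrthologGroup(gid, frozenset(members), _choose_representative(frozenset(members)))
        for gid, members in sorted(raw_groups.items())
    ]


def write_homologene(groups: Iterable[OrthologGroup], path: Path | str) -> None:
    """Serialize groups in the homologene.data dialect (placeholder protein
    columns, deterministic order)."""
    with open(path, "w", encoding="utf-8") as handle:
        for group in sorted(groups, key=lambda g: g.group_id):
            for tax_id, gene_id in sorted(group.members):
                handle.write(
                    f"{group.group_id}\t{tax_id}\t{gene_id}\t"
                    f"GENE{gene_id}\t{gene_id}\tNP_{gene_id:06d}.1\n"
                )


def collapse(
    links: Iterable[GeneLink],
    groups: Iterable[OrthologGroup],
    species: Iterable[int] = DEFAULT_SPECIES,
) -> set[GeneLink]:
    """Replace each gene by its ortholog-group representative.

    Links from species outside ``species`` are removed.  Genes absent from
    every group keep their own identifier (singleton semantics).  The
    resulting link set is duplicate-free, so the operation is idempotent and
    never increases the number of distinct genes.
    """
    species = frozenset(species)
    representative: dict[tuple[int, int], tuple[int, int]] = {}
    for group in groups:
        rep_members = [(t, g) for t, g in group.members if g == group.representative]
        rep_tax = min(t for t, _ in rep_members)
        for member in group.members:
            representative[member] = (rep_tax, group.representative)

    collapsed: set[GeneLink] = set()
    for link in links:
        if link.tax_id not in species:
            continue
        tax_id, gene_id = representative.get(
            (link.tax_id, link.gene_id), (link.tax_id, link.gene_id)
        )
        collapsed.add(GeneLink(tax_id, gene_id, link.pmid))
    return collapsed
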