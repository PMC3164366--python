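"""Cross-species signature construction via homolog mapping.

A directional signature — the up- and down-regulated gene sets one species'
list comparison selected — is carried into another species through a
homolog table (HomoloGene-style, possibly many-to-many).  A homolog pair
whose two endpoints changed in the same direction in their respective
species is *concordant* and enters the conserved signature; a pair whose
endpoints disagree is *discordant* and is reported separately rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .core import ComparisonResult
from .errors import ContractError

__all__ = [
    "HomologMap",
    "DirectionalSignature",
    "ConservedSignature",
    "restrict_to_homologs",
    "conserved_signature",
]


@dataclass
class HomologMap:
    """Bidirectional gene correspondence between species A and species B.

    ``pairs`` holds (species_a_gene, species_b_gene) tuples; the relation
    may be many-to-many and is queried in either direction.
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ContractError("homolog map contains duplicate pairs")
        self._a_to_b: dict[str, set[str]] = {}
        self._b_to_a: dict[str, set[str]] = {}
        for ga, gb in self.pairs:
            self._a_to_b.setdefault(ga, set()).add(gb)
            self._b_to_a.setdefault(gb, set()).add(ga)

    def __len__(self) -> int:
        return len(self.pairs)

    def homologs_of_a(self, gene: str) -> set[str]:
        return set(self._a_to_b.get(gene, ()))

    def homologs_of_b(self, gene: str) -> set[str]:
        return set(self._b_to_a.get(gene, ()))

    def reversed(self) -> "HomologMap":
        return HomologMap(pairs=[(gb, ga) for ga, gb in self.pairs])

    @classmethod
    def from_groups(cls, rows: Iterable[tuple[str, str, str]]) -> "HomologMap":
        """Build from (gene_a, gene_b, group_id) rows: within each group the
        pairs are the cross product of its A genes and its B genes."""
        groups: dict[str, tuple[set, set]] = {}
        for ga, gb, gid in rows:
            a_set, b_set = groups.setdefault(gid, (set(), set()))
            a_set.add(ga)
            b_set.add(gb)
        pairs = sorted(
            (ga, gb)
            for a_set, b_set in groups.values()
            for ga in a_set for gb in b_set
        )
        return cls(pairs=pairs)


@dataclass
class DirectionalSignature:
    """Up- and down-regulated gene sets selected in one species."""

    species: str
    up_genes: set[str]
    down_genes: set[str]

    def __post_init__(self) -> None:
        self.up_genes = set(self.up_genes)
        self.down_genes = set(self.down_genes)
        clash = self.up_genes & self.down_genes
        if clash:
            raise ContractError(f"genes in both directions: {sorted(clash)[:5]}")

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    @classmethod
    def from_results(
        cls, up: ComparisonResult, down: ComparisonResult, species: str
    ) -> "DirectionalSignature":
        return cls(species=species, up_genes=set(up.common_genes),
                   down_genes=set(down.common_genes))


@dataclass
class ConservedSignature:
    """Concordant (and discordant) homolog pairs between two signatures.

    Pairs are the unit of account; ``up_genes``/``down_genes`` render them
    as reporting-species gene ids (a gene with several concordant homologs
    appears once).
    """

    report_species: Literal["a", "b"]
    up_pairs: set[tuple[str, str]]
    down_pairs: set[tuple[str, str]]
    discordant_pairs: set[tuple[str, str]]

    def _render(self, pairs: set[tuple[str, str]]) -> set[str]:
        i = 0 if self.report_species == "a" else 1
        return {p[i] for p in pairs}

    @property
    def up_genes(self) -> set[str]:
        return self._render(self.up_pairs)

    @property
    def down_genes(self) -> set[str]:
        return self._render(self.down_pairs)

    @property
    def discordant_genes(self) -> set[str]:
        return self._render(self.discordant_pairs)

    def as_signature(self, species: str) -> DirectionalSignature:
        return DirectionalSignature(
            species=species, up_genes=self.up_genes, down_genes=self.down_genes
        )


def restrict_to_homologs(
    sig: DirectionalSignature, hmap: HomologMap, side: Literal["a", "b"] = "a"
) -> DirectionalSignature:
    """Keep only signature genes with at least one homolog in the other
    species; direction labels are untouched.  ``side`` states which species
    of the map the signature belongs to.  An empty map yields an empty
    signature (legitimately: nothing maps)."""
    lookup = hmap.homologs_of_a if side == "a" else hmap.homologs_of_b
    return DirectionalSignature(
        species=sig.species,
        up_genes={g for g in sig.up_genes if lookup(g)},
        down_genes={g for g in sig.down_genes if lookup(g)},
    )


def conserved_signature(
    sig_a: DirectionalSignature,
    sig_b: DirectionalSignature,
    hmap: HomologMap,
    report_species: Literal["a", "b"] = "b",
) -> ConservedSignature:
    """Intersect two species' signatures through the homolog map.

    A homolog pair (g_a, g_b) with both endpoints inside their species'
    signature is concordant-up iff both genes are up-regulated,
    concordant-down iff both are down-regulated, and discordant otherwise.
    Counting at the pair level means a gene with several homologs
    contributes whenever ANY of its homologs agrees in direction; the
    discordant pairs are preserved for inspection.
    """
    up: set[tuple[str, str]] = set()
    down: set[tuple[str, str]] = set()
    disc: set[tuple[str, str]] = set()
    a_all = sig_a.up_genes | sig_a.down_genes
    b_all = sig_b.up_genes | sig_b.down_genes
    for ga, gb in hmap.pairs:
        if ga not in a_all or gb not in b_all:
            continue
        a_up = ga in sig_a.up_genes
        b_up = gb in sig_b.up_genes
        if a_up and b_up:
            up.add((ga, gb))
        elif not a_up and not b_up:
            down.add((ga, gb))
        else:
            disc.add((ga, gb))
    return ConservedSignature(
        report_species=report_species, up_pairs=up, down_pairs=down, discordant_pairs=disc
    )
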