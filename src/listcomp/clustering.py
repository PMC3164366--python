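"""Cluster experimental conditions by pairwise ranked-list overlap.

The similarity between two conditions i and j is the number of genes
``k_ij`` their list comparison placed in the common set (up- plus
down-regulated by default; 0 when the comparison found no significant
overlap).  Distances are

    d_ij = max over all off-diagonal pairs (l, m) of k_lm  −  k_ij,

so the most strongly overlapping pair sits at distance 0.  Conditions are
then joined by agglomerative complete linkage and the dendrogram can be
serialized as Newick with branch lengths derived from merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import ComparisonResult
from .errors import ContractError

__all__ = [
    "OverlapDistanceMatrix",
    "Dendrogram",
    "build_distance_matrix",
    "complete_linkage",
]


@dataclass
class OverlapDistanceMatrix:
    """Pairwise overlap counts and the derived clustering distances."""

    condition_labels: list[str]
    k_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.k_matrix = np.asarray(self.k_matrix, dtype=float)
        c = len(self.condition_labels)
        if self.k_matrix.shape != (c, c):
            raise ContractError("k_matrix must be square over the condition labels")
        if not np.allclose(self.k_matrix, self.k_matrix.T):
            raise ContractError("k_matrix must be symmetric")
        off = ~np.eye(c, dtype=bool)
        if np.any(self.k_matrix[off] < 0):
            raise ContractError("overlap counts cannot be negative")

    @property
    def d_matrix(self) -> np.ndarray:
        """max off-diagonal k minus k_ij; diagonal fixed at 0."""
        c = len(self.condition_labels)
        off = ~np.eye(c, dtype=bool)
        kmax = float(self.k_matrix[off].max())
        d = kmax - self.k_matrix
        np.fill_diagonal(d, 0.0)
        return d


def _pair_overlap(value) -> int:
    """Total common-gene count from one pair's comparison output."""
    if isinstance(value, ComparisonResult):
        return value.overlap_size
    if isinstance(value, (int, np.integer)):
        return int(value)
    try:
        return sum(r.overlap_size for r in value)
    except TypeError:
        raise ContractError(
            f"cannot extract an overlap count from {type(value).__name__}"
        ) from None


def build_distance_matrix(
    labels: Sequence[str],
    pair_results: Mapping[tuple[str, str], object],
) -> OverlapDistanceMatrix:
    """Assemble the overlap matrix from all pairwise comparison results.

    ``pair_results`` maps unordered condition pairs to either a single
    ``ComparisonResult``, a sequence of them (e.g. the up/down pair from
    ``compare_directional``, whose common-set sizes are summed), or a plain
    overlap count.  Every unordered pair of ``labels`` must be present under
    either key orientation; missing pairs are reported together.
    """
    labels = list(labels)
    if len(labels) != len(set(labels)):
        raise ContractError("condition labels must be unique")
    c = len(labels)
    if c < 2:
        raise ContractError("need at least two conditions")
    idx = {lab: i for i, lab in enumerate(labels)}
    k = np.zeros((c, c))
    seen: set[frozenset] = set()
    for (a, b), value in pair_results.items():
        if a not in idx or b not in idx:
            raise ContractError(f"pair ({a!r}, {b!r}) refers to unknown conditions")
        if a == b:
            continue
        kij = _pair_overlap(value)
        k[idx[a], idx[b]] = kij
        k[idx[b], idx[a]] = kij
        seen.add(frozenset((a, b)))
    missing = [
        (labels[i], labels[j])
        for i in range(c) for j in range(i + 1, c)
        if frozenset((labels[i], labels[j])) not in seen
    ]
    if missing:
        raise ContractError(f"missing pairwise comparisons: {missing}")
    return OverlapDistanceMatrix(condition_labels=labels, k_matrix=k)


@dataclass
class Dendrogram:
    """A complete-linkage tree over the conditions."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (C-1) x 4

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster assignment label -> cluster id (1-based)."""
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(x) for x in flat)))

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        inner = render(root, root.dist)  # root branch length 0
        return inner + ";"


def complete_linkage(dist: OverlapDistanceMatrix, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the conditions (complete linkage default).

    Merge heights are non-decreasing for complete linkage.  Ties are
    resolved deterministically by the order of ``condition_labels``.
    Alternative linkage criteria may be selected via ``method`` but the
    overlap-distance construction is only characterized for complete
    linkage.
    """
    if len(dist.condition_labels) < 2:
        raise ContractError("need at least two conditions to cluster")
    z = hierarchy.linkage(squareform(dist.d_matrix, checks=False), method=method)
    return Dendrogram(labels=list(dist.condition_labels), linkage=z)
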