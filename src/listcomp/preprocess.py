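"""From replicate expression matrices to directional ranked gene lists.

The pipeline consumes already-normalized log2 expression scores (probesets x
replicates) for one treatment/control pair and produces, per direction of
change, a gene list ranked by the magnitude of the log2 fold-change.  Three
rules shape the result:

1. probesets expressed below the ``percentile``-th quantile of per-probeset
   mean expression in *both* conditions are discarded (lowly expressed in
   treatment AND control);
2. the probeset fold-change is the difference of log2 replicate means
   (treatment minus control), and probesets interrogating the same gene are
   collapsed by averaging their fold-changes;
3. genes are ranked by |log2 fold-change| within their direction of change;
   zero-change genes belong to neither directional list but still count
   toward the universe size N used by the overlap statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError

__all__ = [
    "ExpressionMatrix",
    "FoldChangeTable",
    "RankedGeneList",
    "filter_low_expression",
    "compute_fold_changes",
    "rank_genes",
]

TREATMENT = "treatment"
CONTROL = "control"

Direction = Literal["up", "down"]


@dataclass
class ExpressionMatrix:
    """Log2 expression scores, probesets x replicates, for one condition pair.

    ``gene_symbols`` carries one symbol per probeset and may repeat (several
    probesets interrogating the same gene); ``probeset_ids`` are unique.
    """

    probeset_ids: list[str]
    gene_symbols: list[str]
    scores: np.ndarray
    condition_labels: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ContractError("scores must be a 2-D probesets x replicates matrix")
        if self.scores.shape != (len(self.probeset_ids), len(self.condition_labels)):
            raise ContractError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.probeset_ids)} probesets x {len(self.condition_labels)} samples"
            )
        if len(self.gene_symbols) != len(self.probeset_ids):
            raise ContractError("one gene symbol per probeset required")
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ContractError("probeset ids must be unique")
        bad = set(self.condition_labels) - {TREATMENT, CONTROL}
        if bad:
            raise ContractError(f"unknown condition labels: {sorted(bad)}")
        if TREATMENT not in self.condition_labels or CONTROL not in self.condition_labels:
            raise ContractError("need at least one treatment and one control column")
        if not np.all(np.isfinite(self.scores)):
            raise ContractError("scores contain missing or non-finite values")

    @property
    def treatment_cols(self) -> np.ndarray:
        return np.array([c == TREATMENT for c in self.condition_labels])

    @property
    def control_cols(self) -> np.ndarray:
        return np.array([c == CONTROL for c in self.condition_labels])

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)


@dataclass
class FoldChangeTable:
    """One signed log2 fold-change per gene symbol."""

    genes: np.ndarray
    fold_change: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        if self.genes.shape != self.fold_change.shape or self.genes.ndim != 1:
            raise ContractError("genes and fold_change must be parallel 1-D arrays")
        if len(set(self.genes)) != len(self.genes):
            raise ContractError("one row per gene symbol required")
        if not np.all(np.isfinite(self.fold_change)):
            raise ContractError("fold changes must be finite")

    def __len__(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.fold_change, index=self.genes, name="fold_change")

    def restrict(self, genes: Sequence[str]) -> "FoldChangeTable":
        """Subset to ``genes`` (order follows the given sequence)."""
        s = self.as_series()
        missing = [g for g in genes if g not in s.index]
        if missing:
            raise ContractError(f"genes absent from table: {missing[:5]}...")
        sub = s.loc[list(genes)]
        return FoldChangeTable(genes=np.asarray(sub.index, dtype=object),
                               fold_change=sub.to_numpy())

    @classmethod
    def from_series(cls, s: pd.Series) -> "FoldChangeTable":
        return cls(genes=np.asarray(s.index, dtype=object), fold_change=s.to_numpy(dtype=float))


@dataclass
class RankedGeneList:
    """Genes ordered by |log2 fold-change| in one direction of change.

    ``universe_size`` is the number of genes that survived filtering — the
    hypergeometric population N — and is at least ``len(genes)`` because
    genes changing in the other direction (or not at all) still count.
    """

    direction: Direction
    genes: list[str]
    magnitudes: np.ndarray
    universe_size: int

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.direction not in ("up", "down"):
            raise ContractError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if len(self.genes) != len(self.magnitudes):
            raise ContractError("genes and magnitudes must be parallel")
        if len(self.genes) > self.universe_size:
            raise ContractError("list longer than its universe")
        if len(set(self.genes)) != len(self.genes):
            raise ContractError("ranked genes must be unique")
        if len(self.magnitudes) > 1 and np.any(np.diff(self.magnitudes) > 1e-12):
            raise ContractError("magnitudes must be non-increasing along the ranking")
        if np.any(self.magnitudes < 0):
            raise ContractError("magnitudes are absolute values and cannot be negative")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, m: int) -> list[str]:
        return self.genes[:m]


def filter_low_expression(mat: ExpressionMatrix, percentile: float = 0.25) -> ExpressionMatrix:
    """Drop probesets lowly expressed in both conditions.

    A probeset is removed iff its mean treatment score is strictly below the
    ``percentile``-th quantile of all per-probeset mean treatment scores AND
    its mean control score is strictly below the corresponding control
    quantile.  Quantiles use linear interpolation (the numpy default).
    Order of the retained probesets is preserved.
    """
    if not 0.0 < percentile < 1.0:
        raise ContractError(f"percentile must be in (0, 1), got {percentile}")
    t_means = mat.scores[:, mat.treatment_cols].mean(axis=1)
    c_means = mat.scores[:, mat.control_cols].mean(axis=1)
    qt = np.quantile(t_means, percentile)
    qc = np.quantile(c_means, percentile)
    keep = ~((t_means < qt) & (c_means < qc))
    if not keep.any():
        raise DegenerateInputError("low-expression filter removed every probeset")
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        probeset_ids=[mat.probeset_ids[i] for i in idx],
        gene_symbols=[mat.gene_symbols[i] for i in idx],
        scores=mat.scores[idx],
        condition_labels=list(mat.condition_labels),
    )


def compute_fold_changes(
    mat: ExpressionMatrix, mode: Literal["log_diff", "raw_ratio"] = "log_diff"
) -> FoldChangeTable:
    """Per-gene fold-changes from a (filtered) expression matrix.

    ``log_diff`` (default, recommended): fold-change = mean(log2 treatment)
    − mean(log2 control), i.e. the log2 ratio of geometric means — the
    conventional log2 fold-change.  ``raw_ratio`` divides the log2-score
    means literally; it is exposed for completeness but its values are
    centred at 1, not 0, so it does not feed the directional ranking.

    Genes measured by several probesets get the arithmetic mean of their
    probesets' fold-changes.
    """
    t_means = mat.scores[:, mat.treatment_cols].mean(axis=1)
    c_means = mat.scores[:, mat.control_cols].mean(axis=1)
    if mode == "log_diff":
        probe_fc = t_means - c_means
    elif mode == "raw_ratio":
        probe_fc = t_means / c_means
    else:
        raise ContractError(f"unknown fold_change_mode {mode!r}")
    per_gene = (
        pd.Series(probe_fc, index=pd.Index(mat.gene_symbols, name="gene"))
        .groupby(level=0, sort=True)
        .mean()
    )
    return FoldChangeTable.from_series(per_gene)


def rank_genes(fc: FoldChangeTable, direction: Direction) -> RankedGeneList:
    """Rank one direction of change by |log2 fold-change|, strongest first.

    Up-lists take fold_change > 0, down-lists fold_change < 0; exact zeros
    join neither list but remain part of the universe N.  Ties in magnitude
    break lexicographically by gene symbol so every downstream step is
    deterministic.
    """
    if len(fc) == 0:
        raise ContractError("cannot rank an empty fold-change table")
    if direction == "up":
        sel = fc.fold_change > 0
    elif direction == "down":
        sel = fc.fold_change < 0
    else:
        raise ContractError(f"direction must be 'up' or 'down', got {direction!r}")
    genes = fc.genes[sel]
    mags = np.abs(fc.fold_change[sel])
    order = sorted(range(len(genes)), key=lambda i: (-mags[i], genes[i]))
    return RankedGeneList(
        direction=direction,
        genes=[genes[i] for i in order],
        magnitudes=mags[order] if len(order) else np.empty(0),
        universe_size=len(fc),
    )
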