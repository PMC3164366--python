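"""The stepwise marching comparison of two ranked gene lists.

Starting from the top ``step`` ranks of each list, the algorithm counts the
genes the two top blocks share, tests that overlap against the
hypergeometric null, then repeatedly deepens both blocks by ``step`` ranks.
It stops the first time either criterion fails:

1. the overlap of the current top blocks is not significant
   (``overlap_pvalue >= alpha``); or
2. the growth of the overlap since the previous step is explainable by
   random rank assignment (``increment_pvalue >= alpha``; not applied at the
   first step, which has no predecessor).

The selected depth ``m*`` is the deepest step at which both criteria held;
the common gene set is the intersection of the two top-``m*`` blocks.  If
the very first step already fails, the verdict is ``no_significant_overlap``
and the common set is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ContractError
from .overlap_stats import IncrementTest, OverlapTest, increment_pvalue, overlap_pvalue
from .preprocess import Direction, FoldChangeTable, RankedGeneList, rank_genes

__all__ = [
    "StepRecord",
    "ComparisonResult",
    "DirectionVenn",
    "VennSummary",
    "compare_lists",
    "compare_directional",
    "venn_counts",
    "SIGNIFICANT",
    "NOT_SIGNIFICANT",
]

SIGNIFICANT = "significant_overlap"
NOT_SIGNIFICANT = "no_significant_overlap"


@dataclass(frozen=True)
class StepRecord:
    """One evaluated depth of the march: the (m, k) point of the step trace."""

    m: int
    k: int
    overlap_p: float
    increment_p: Optional[float]  # absent at the first step
    significant: bool


@dataclass
class ComparisonResult:
    """Outcome of one directional list comparison."""

    direction: Direction
    universe_size: int
    step: int
    alpha: float
    selected_depth: int
    common_genes: list[str]
    trace: list[StepRecord]
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in (SIGNIFICANT, NOT_SIGNIFICANT):
            raise ContractError(f"unknown verdict {self.verdict!r}")
        if self.verdict == NOT_SIGNIFICANT and (self.common_genes or self.selected_depth):
            raise ContractError("a non-significant result carries no genes and depth 0")

    @property
    def overlap_size(self) -> int:
        return len(self.common_genes)


def _validate_pair(list_a: RankedGeneList, list_b: RankedGeneList, step: int) -> None:
    if list_a.direction != list_b.direction:
        raise ContractError(
            f"directions differ: {list_a.direction!r} vs {list_b.direction!r}"
        )
    if list_a.universe_size != list_b.universe_size:
        raise ContractError(
            f"universes differ: N={list_a.universe_size} vs N={list_b.universe_size}; "
            "restrict both lists to the shared measured universe first"
        )
    if step <= 0:
        raise ContractError(f"step must be positive, got {step}")
    if not list_a.genes or not list_b.genes:
        raise ContractError("both lists must be non-empty")


def _empty_result(direction: Direction, n: int, step: int, alpha: float,
                  trace: list[StepRecord] | None = None) -> ComparisonResult:
    return ComparisonResult(
        direction=direction, universe_size=n, step=step, alpha=alpha,
        selected_depth=0, common_genes=[], trace=trace or [], verdict=NOT_SIGNIFICANT,
    )


def compare_lists(
    list_a: RankedGeneList,
    list_b: RankedGeneList,
    step: int = 100,
    alpha: float = 0.05,
    *,
    bonferroni_steps: bool = False,
) -> ComparisonResult:
    """March down two ranked lists and select the deepest significant overlap.

    Parameters
    ----------
    list_a, list_b : ranked lists sharing a direction and a universe size N.
    step : ranks added to each list per step (a shorter final step covers the
        remainder when the list length is not a multiple; a step larger than
        the shortest list collapses to a single evaluation at that length).
    alpha : significance level applied to both criteria, raw per step.
    bonferroni_steps : divide alpha by the number of scheduled steps
        (off by default: the procedure is sequential with raw p-values).
    """
    _validate_pair(list_a, list_b, step)
    n = list_a.universe_size
    limit = min(len(list_a), len(list_b))
    depths = list(range(step, limit + 1, step))
    if not depths or depths[-1] != limit:
        depths.append(limit)
    threshold = alpha / len(depths) if bonferroni_steps else alpha

    in_a: set[str] = set()
    in_b: set[str] = set()
    k = 0
    trace: list[StepRecord] = []
    prev: Optional[OverlapTest] = None
    m_star, k_star = 0, 0
    done = 0
    for m in depths:
        for g in list_a.genes[done:m]:
            in_a.add(g)
            if g in in_b:
                k += 1
        for g in list_b.genes[done:m]:
            in_b.add(g)
            if g in in_a:
                k += 1
        done = m
        test = overlap_pvalue(n, m, k)
        ok = test.p_value < threshold
        inc: Optional[IncrementTest] = None
        if ok and prev is not None:
            inc = increment_pvalue(prev, m, k)
            ok = inc.delta_p_value < threshold
        trace.append(StepRecord(
            m=m, k=k, overlap_p=test.p_value,
            increment_p=None if inc is None else inc.delta_p_value,
            significant=ok,
        ))
        if not ok:
            break
        prev = test
        m_star, k_star = m, k

    if m_star == 0:
        return _empty_result(list_a.direction, n, step, alpha, trace)
    common = sorted(set(list_a.genes[:m_star]) & set(list_b.genes[:m_star]))
    assert len(common) == k_star
    return ComparisonResult(
        direction=list_a.direction, universe_size=n, step=step, alpha=alpha,
        selected_depth=m_star, common_genes=common, trace=trace, verdict=SIGNIFICANT,
    )


def compare_directional(
    fc_a: FoldChangeTable,
    fc_b: FoldChangeTable,
    step: int = 100,
    alpha: float = 0.05,
) -> tuple[ComparisonResult, ComparisonResult]:
    """Compare two experiments' fold-change tables, up- and down-lists apart.

    Both tables are first restricted to their shared gene universe (genes
    measured on both platforms); N is the shared-universe size.  Returns the
    (up, down) pair of results; the union of their common gene sets is the
    two experiments' joint signature.
    """
    shared = sorted(set(fc_a.genes) & set(fc_b.genes))
    if not shared:
        raise ContractError("the two tables share no genes")
    sub_a = fc_a.restrict(shared)
    sub_b = fc_b.restrict(shared)
    results = []
    for direction in ("up", "down"):
        la = rank_genes(sub_a, direction)
        lb = rank_genes(sub_b, direction)
        if len(la) == 0 or len(lb) == 0:
            results.append(_empty_result(direction, len(shared), step, alpha))
        else:
            results.append(compare_lists(la, lb, step=step, alpha=alpha))
    return results[0], results[1]


@dataclass(frozen=True)
class DirectionVenn:
    """Venn counts at the selected depth for one direction."""

    a_only: int
    common: int
    b_only: int
    verdict: str


@dataclass(frozen=True)
class VennSummary:
    up: Optional[DirectionVenn]
    down: Optional[DirectionVenn]


def _direction_venn(result: ComparisonResult) -> Optional[DirectionVenn]:
    if result.verdict == NOT_SIGNIFICANT:
        return None
    k = result.overlap_size
    m = result.selected_depth
    return DirectionVenn(a_only=m - k, common=k, b_only=m - k, verdict=result.verdict)


def venn_counts(result_up: ComparisonResult, result_down: ComparisonResult) -> VennSummary:
    """Per-direction Venn counts (A-only, common, B-only) at depth m*.

    Both lists contribute m* genes at the selected depth, so the private
    counts are m* − k* on each side.  A direction with no significant
    overlap yields no Venn; the verdict is propagated as ``None``.
    """
    return VennSummary(up=_direction_venn(result_up), down=_direction_venn(result_down))
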