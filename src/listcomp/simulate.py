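"""Synthetic ranked-list pairs, fold-change tables and expression matrices.

The two shuffles reproduce the classic validation design for ranked-list
overlap tests: an unconstrained shuffle of list A yields an unrelated list B
(the null regime), while a window-constrained shuffle — every gene may move
at most ``window`` ranks — yields a strongly related pair whose top blocks
overlap heavily (the power regime).  ``make_related_tables`` plants a known
shared signature into two fold-change tables for parameter-recovery tests,
and ``make_expression_matrix`` expands a fold-change table back into a
replicate-level expression matrix so the whole pipeline can run end to end
without any external dataset.

All generators take an integer seed (or a ``numpy.random.Generator``) and
are exactly reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ContractError
from .preprocess import Direction, ExpressionMatrix, FoldChangeTable, RankedGeneList

__all__ = [
    "ShuffleSpec",
    "make_ranked_list",
    "shuffle_unconstrained",
    "shuffle_windowed",
    "make_related_tables",
    "make_expression_matrix",
    "make_tissue_panel",
]


@dataclass(frozen=True)
class ShuffleSpec:
    """Parameters of a list-B construction from list A."""

    N: int
    mode: Literal["unconstrained", "windowed"]
    window: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode == "windowed" and not 1 <= self.window < self.N:
            raise ContractError(
                f"windowed mode requires 1 <= window < N, got window={self.window}, N={self.N}"
            )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_ranked_list(
    N: int, seed, direction: Direction = "up", n_ranked: int | None = None
) -> RankedGeneList:
    """A synthetic ranked list over a universe of N genes.

    By default all N genes are ranked (list A of the shuffle designs — a
    complete ranking of the universe, under which the overlap null of the
    marching test is exactly calibrated).  ``n_ranked`` restricts the list
    to the top ``n_ranked`` genes, mimicking a directional list that covers
    only part of the measured universe.  Magnitudes are |Normal(0, 1)|
    draws sorted descending.
    """
    if N < 1:
        raise ContractError("need at least one gene")
    L = N if n_ranked is None else n_ranked
    if not 1 <= L <= N:
        raise ContractError(f"n_ranked must be in [1, N], got {n_ranked}")
    rng = _rng(seed)
    genes = _gene_names(N)
    rng.shuffle(genes)
    mags = np.sort(np.abs(rng.normal(0.0, 1.0, size=L)))[::-1]
    return RankedGeneList(direction=direction, genes=list(genes[:L]),
                          magnitudes=mags, universe_size=N)


def shuffle_unconstrained(list_a: RankedGeneList, seed) -> RankedGeneList:
    """Uniform random permutation of the gene order; magnitudes keep their
    rank profile so the output is a valid ranked list over the same genes."""
    if len(list_a) == 0:
        raise ContractError("cannot shuffle an empty list")
    rng = _rng(seed)
    perm = rng.permutation(len(list_a))
    return RankedGeneList(
        direction=list_a.direction,
        genes=[list_a.genes[i] for i in perm],
        magnitudes=list_a.magnitudes.copy(),
        universe_size=list_a.universe_size,
    )


def shuffle_windowed(list_a: RankedGeneList, window: int, seed) -> RankedGeneList:
    """Random permutation in which no gene moves more than ``window`` ranks.

    Sliding-pool sampler: output ranks are filled left to right; at rank r
    the candidates are the unplaced genes with original rank within
    ``window`` of r, drawn uniformly — except that a gene reaching its
    deadline (original rank r − window) must be placed immediately, which
    keeps the draw feasible.  The displacement bound holds by construction
    and, when ``window = len(list) − 1``, the procedure reduces exactly to a
    Fisher–Yates shuffle (no deadline can force a choice before the last
    rank), i.e. the unconstrained uniform distribution.
    """
    L = len(list_a)
    if not 1 <= window < L:
        raise ContractError(f"need 1 <= window < list length, got window={window}, L={L}")
    rng = _rng(seed)
    pool: list[int] = []          # original ranks currently available
    pos: dict[int, int] = {}      # original rank -> index in pool
    order: list[int] = []
    nxt = 0
    for r in range(L):
        while nxt < L and nxt <= r + window:
            pos[nxt] = len(pool)
            pool.append(nxt)
            nxt += 1
        deadline = r - window
        if deadline >= 0 and deadline in pos:
            idx = pos[deadline]
        else:
            idx = int(rng.integers(len(pool)))
        chosen = pool[idx]
        last = pool[-1]
        pool[idx] = last
        pos[last] = idx
        pool.pop()
        del pos[chosen]
        order.append(chosen)
    return RankedGeneList(
        direction=list_a.direction,
        genes=[list_a.genes[i] for i in order],
        magnitudes=list_a.magnitudes.copy(),
        universe_size=list_a.universe_size,
    )


def _gene_names(n: int, prefix: str = "g") -> np.ndarray:
    width = len(str(n - 1))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(n)], dtype=object)


def make_related_tables(
    N: int,
    frac_shared: float,
    effect_size: float,
    noise_sd: float,
    seed,
) -> tuple[FoldChangeTable, FoldChangeTable, list[str]]:
    """Two fold-change tables over the same genes with a planted shared set.

    A fraction ``frac_shared`` of the genes receives a shared signed effect
    (±``effect_size``, sign drawn once per gene and identical in both
    tables); every gene in every table additionally receives independent
    Normal(0, ``noise_sd``) noise.  Returns (table_a, table_b, planted
    genes) so recovery can be scored.
    """
    if not 0.0 <= frac_shared <= 1.0:
        raise ContractError(f"frac_shared must be in [0, 1], got {frac_shared}")
    rng = _rng(seed)
    genes = _gene_names(N)
    n_planted = int(round(frac_shared * N))
    planted_idx = rng.choice(N, size=n_planted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    base = np.zeros(N)
    base[planted_idx] = signs * effect_size
    fc_a = base + (rng.normal(0.0, noise_sd, size=N) if noise_sd > 0 else 0.0)
    fc_b = base + (rng.normal(0.0, noise_sd, size=N) if noise_sd > 0 else 0.0)
    planted = sorted(genes[i] for i in planted_idx)
    return (
        FoldChangeTable(genes=genes.copy(), fold_change=fc_a),
        FoldChangeTable(genes=genes.copy(), fold_change=fc_b),
        planted,
    )


def make_expression_matrix(
    fc: FoldChangeTable,
    replicates: int = 3,
    probes_per_gene: int = 1,
    noise_sd: float = 0.0,
    seed=0,
    baseline: float = 8.0,
) -> ExpressionMatrix:
    """Expand a fold-change table into a replicate-level log2 matrix.

    Control replicates sit at ``baseline``, treatment replicates at
    ``baseline + fold_change``; each probeset replicate gets independent
    Normal(0, ``noise_sd``) noise.  Genes expand to ``probes_per_gene``
    probesets named ``<gene>_p<j>`` so the collapsing rule is exercised.
    With ``noise_sd = 0`` the preprocessing round trip recovers ``fc``
    exactly.
    """
    if replicates < 1:
        raise ContractError("need at least one replicate per condition")
    if probes_per_gene < 1:
        raise ContractError("need at least one probeset per gene")
    rng = _rng(seed)
    n_probes = len(fc) * probes_per_gene
    probeset_ids = [
        f"{g}_p{j}" for g in fc.genes for j in range(probes_per_gene)
    ]
    gene_symbols = [g for g in fc.genes for _ in range(probes_per_gene)]
    probe_fc = np.repeat(fc.fold_change, probes_per_gene)
    treat = baseline + probe_fc[:, None] + np.zeros((n_probes, replicates))
    ctrl = baseline + np.zeros((n_probes, replicates))
    if noise_sd > 0:
        treat = treat + rng.normal(0.0, noise_sd, size=treat.shape)
        ctrl = ctrl + rng.normal(0.0, noise_sd, size=ctrl.shape)
    scores = np.hstack([treat, ctrl])
    labels = ["treatment"] * replicates + ["control"] * replicates
    return ExpressionMatrix(
        probeset_ids=probeset_ids,
        gene_symbols=gene_symbols,
        scores=scores,
        condition_labels=labels,
    )


def make_tissue_panel(
    n_tissues: int = 2,
    conditions_per_tissue: int = 3,
    N: int = 2000,
    signature_size: int = 300,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    seed=0,
) -> tuple[dict[str, FoldChangeTable], dict[str, str]]:
    """A panel of experimental conditions with a dominant tissue effect.

    Each tissue owns a disjoint planted signature of ``signature_size``
    genes with fixed signs; every condition of that tissue expresses the
    signature (± independent noise), so within-tissue pairs share many genes
    and between-tissue pairs share essentially none.  Returns (label →
    fold-change table, label → tissue).
    """
    if n_tissues * signature_size > N:
        raise ContractError("tissue signatures must fit disjointly in the universe")
    rng = _rng(seed)
    genes = _gene_names(N)
    block = rng.permutation(N)
    tables: dict[str, FoldChangeTable] = {}
    tissue_of: dict[str, str] = {}
    for t in range(n_tissues):
        sig_idx = block[t * signature_size:(t + 1) * signature_size]
        signs = rng.choice([-1.0, 1.0], size=signature_size)
        for c in range(conditions_per_tissue):
            label = f"tissue{t}_cond{c}"
            fc = rng.normal(0.0, noise_sd, size=N)
            fc[sig_idx] += signs * effect_size
            tables[label] = FoldChangeTable(genes=genes.copy(), fold_change=fc)
            tissue_of[label] = f"tissue{t}"
    return tables, tissue_of
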