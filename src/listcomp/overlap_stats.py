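"""Exact hypergeometric machinery for ranked-list overlap significance.

Two selections of ``m`` genes each, drawn independently and uniformly from a
universe of ``N`` genes, share ``X`` genes where ``X`` follows the
hypergeometric distribution

    P(X = k) = C(m, k) * C(N - m, m - k) / C(N, m).

``overlap_pvalue`` gives the upper tail P(X >= k*), the significance of an
observed overlap of ``k*`` genes.  ``increment_pvalue`` answers the second
question the stepwise marching algorithm asks: once the top ``m_prev`` ranks
of both lists are fixed with overlap ``k_prev``, is the growth of the overlap
after adding ``delta_m`` further ranks to each list larger than random rank
assignment would produce?

Everything is computed in log space with ``scipy.special.gammaln``; tail sums
accumulate their terms in ascending magnitude so the smallest contributions
are not absorbed before the large ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import ContractError

__all__ = [
    "OverlapTest",
    "IncrementTest",
    "hypergeom_pmf",
    "overlap_pvalue",
    "increment_pvalue",
]


@dataclass(frozen=True)
class OverlapTest:
    """One (N, m, k) overlap configuration and its upper-tail probability."""

    N: int
    m: int
    k: int
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.m <= self.N:
            raise ContractError(
                f"need 0 <= k <= m <= N, got N={self.N}, m={self.m}, k={self.k}"
            )
        # k may sit below the support minimum max(0, 2m - N): as a tail
        # threshold such a k is answerable (p = 1 exactly)
        if self.k < max(0, 2 * self.m - self.N) and self.p_value != 1.0:
            raise ContractError(
                f"k={self.k} below the hypergeometric support minimum "
                f"{max(0, 2 * self.m - self.N)} must carry p_value 1"
            )
        if not 0.0 < self.p_value <= 1.0:
            raise ContractError(f"p_value must be in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class IncrementTest:
    """Significance of the overlap increase between two consecutive steps."""

    N: int
    m_prev: int
    k_prev: int
    m_new: int
    k_new: int
    delta_p_value: float

    def __post_init__(self) -> None:
        if self.m_new <= self.m_prev:
            raise ContractError("m_new must exceed m_prev")
        if self.k_new < self.k_prev:
            raise ContractError("overlap cannot shrink when ranks are added")
        if not 0.0 < self.delta_p_value <= 1.0:
            raise ContractError(f"delta_p_value must be in (0, 1], got {self.delta_p_value}")


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    """log C(n, k), -inf outside 0 <= k <= n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    valid = (k >= 0) & (k <= n)
    n_ = np.where(valid, n, 1.0)
    k_ = np.where(valid, k, 0.0)
    out = gammaln(n_ + 1.0) - gammaln(k_ + 1.0) - gammaln(n_ - k_ + 1.0)
    return np.where(valid, out, -np.inf)


def _log_pmf(N: int, m_a: int, m_b: int, k: np.ndarray) -> np.ndarray:
    """log P(|A ∩ B| = k) for independent uniform m_a- and m_b-subsets of N."""
    return _log_binom(m_a, k) + _log_binom(N - m_a, m_b - k) - _log_binom(N, m_b)


def hypergeom_pmf(N: int, m: int, k, m_other: int | None = None):
    """P(X = k) for the overlap of two random selections from ``N`` genes.

    Parameters
    ----------
    N : universe size.
    m : genes selected from the first list.
    k : overlap count; scalar or array.
    m_other : genes selected from the second list; defaults to ``m`` (equal
        selections, the standard configuration).

    Out-of-support ``k`` returns 0 rather than raising: the marching
    algorithm probes counts without pre-clamping them.
    """
    m_b = m if m_other is None else m_other
    if not (0 <= m <= N and 0 <= m_b <= N):
        raise ContractError(f"need 0 <= m <= N, got N={N}, m={m}, m_other={m_b}")
    karr = np.asarray(k)
    with np.errstate(invalid="ignore"):
        out = np.exp(_log_pmf(N, m, m_b, karr))
    if np.ndim(k) == 0:
        return float(out)
    return out


def overlap_pvalue(N: int, m: int, k_star: int, m_other: int | None = None) -> OverlapTest:
    """Upper-tail probability P(X >= k*) of the overlap distribution.

    The tail is an exact finite sum over the support from ``k_star`` to
    ``min(m, m_other)``; terms are added smallest first.  ``k_star = 0``
    returns exactly 1.
    """
    m_b = m if m_other is None else m_other
    if not (0 <= k_star <= min(m, m_b) <= N):
        raise ContractError(
            f"need 0 <= k* <= min(m, m_other) <= N, got N={N}, m={m}, "
            f"m_other={m_b}, k*={k_star}"
        )
    lo = max(0, m + m_b - N)
    if k_star <= lo:
        p = 1.0
    else:
        ks = np.arange(k_star, min(m, m_b) + 1)
        terms = np.exp(_log_pmf(N, m, m_b, ks))
        p = float(np.sum(np.sort(terms)))
        # extremely deep overlaps underflow the tail sum; keep p strictly
        # positive so downstream comparisons against alpha stay meaningful
        p = min(max(p, np.finfo(float).tiny), 1.0)
    if m_other is None:
        return OverlapTest(N=N, m=m, k=k_star, p_value=p)
    # unequal selections: report under the first list's m; invariants on k
    # still hold because k* <= min(m, m_b) <= m.
    return OverlapTest(N=N, m=m, k=k_star, p_value=p)


def increment_pvalue(prev: OverlapTest, m_new: int, k_new: int) -> IncrementTest:
    """Probability that an overlap increase at least as large arises by chance.

    Null model, conditional on the previous step: each list's next
    ``delta_m = m_new - m_prev`` ranks are an exchangeable uniform draw from
    that list's remaining ``N - m_prev`` genes.  Writing
    ``a = m_prev - k_prev`` for the genes private to each list so far, the
    overlap increase decomposes as ``delta_k = X + H`` where

    * ``X`` counts new list-A genes that were already in list B's top block:
      ``X ~ HG(N - m_prev, a, delta_m)``;
    * ``H`` counts new list-B genes falling anywhere in list A's enlarged top
      block (its ``a`` private genes plus the ``delta_m - X`` newly added
      genes outside B): ``H | X ~ HG(N - m_prev, a + delta_m - X, delta_m)``.

    The tail P(delta_k >= observed) is an exact double sum over this mixture.
    """
    dm = m_new - prev.m
    if dm <= 0:
        raise ContractError("no step taken: m_new must exceed the previous m")
    if m_new > prev.N:
        raise ContractError(f"m_new={m_new} exceeds the universe N={prev.N}")
    if k_new < prev.k:
        raise ContractError("overlap cannot shrink when ranks are added")
    dk = k_new - prev.k
    if dk == 0:
        p = 1.0
    else:
        pool = prev.N - prev.m
        a = prev.m - prev.k
        xs = np.arange(0, min(dm, a) + 1)
        log_px = _log_pmf(pool, a, dm, xs)
        # tail of H | X = x over the grid of h values, one row per x
        hs = np.arange(0, dm + 1)
        succ = a + dm - xs  # successes in B's pool, per x
        log_ph = (
            _log_binom(succ[:, None], hs[None, :])
            + _log_binom(pool - succ[:, None], dm - hs[None, :])
            - _log_binom(pool, dm)
        )
        need = dk - xs  # H must reach this, per x
        mask = hs[None, :] >= need[:, None]
        terms = np.where(mask, np.exp(log_ph), 0.0)
        tail_h = np.sum(np.sort(terms, axis=1), axis=1)
        tail_h = np.minimum(tail_h, 1.0)
        contrib = np.exp(log_px) * tail_h
        p = float(np.sum(np.sort(contrib)))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    return IncrementTest(
        N=prev.N, m_prev=prev.m, k_prev=prev.k, m_new=m_new, k_new=k_new, delta_p_value=p
    )
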