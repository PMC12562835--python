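"""Independent oracles used by the test suite.

Everything here is deliberately implemented apart from the package code
paths it checks: a recursive minimum-mutation search, a from-scratch
hypergeometric enumeration for Fisher's exact test, and closed-form
expectations for what parsimony counting can recover from a stepwise
walk.
"""

from __future__ import annotations

import functools
from math import comb, lgamma, exp

import numpy as np

from ystrped.model import Allele


# ---------------------------------------------------------------------------
# Minimum-mutation cost by recursive scenario enumeration


def _pair_cost(a: Allele, b: Allele) -> int:
    if a.frac != b.frac:
        return 1
    return abs(a.whole - b.whole)


def _match_cost(A: tuple[Allele, ...], B: tuple[Allele, ...]) -> int:
    """Min-cost matching by recursion on the first element (no
    permutation machinery)."""
    if not A:
        return 0
    first, rest = A[0], A[1:]
    return min(
        _pair_cost(first, B[j]) + _match_cost(rest, B[:j] + B[j + 1 :])
        for j in range(len(B))
    )


def _readings(ms: tuple[Allele, ...], expected: int) -> list[tuple[Allele, ...]]:
    outs = {ms}
    stack = [ms]
    while stack:
        cur = stack.pop()
        if len(cur) < expected:
            for a in set(cur):
                nxt = tuple(sorted(cur + (a,)))
                if nxt not in outs:
                    outs.add(nxt)
                    stack.append(nxt)
    return sorted(outs)


def min_mutation_cost(
    A: tuple[Allele, ...], B: tuple[Allele, ...], expected: int
) -> int:
    """Brute-force minimum number of mutations explaining A vs B.

    Enumerates every reading (homoallelic hidden copies up to the
    expected copy number), every choice of gained/lost copies bridging a
    copy-number difference (one mutation each), and every residual
    matching, by plain recursion.
    """
    A, B = tuple(sorted(A)), tuple(sorted(B))
    if A and B and (A[0].is_null or B[0].is_null):
        if A[0].is_null and B[0].is_null:
            return 0
        return 1

    def bridge(small: tuple[Allele, ...], large: tuple[Allele, ...]) -> int:
        if len(small) == len(large):
            return _match_cost(small, large)
        # remove one copy from the larger side, costing one mutation
        return 1 + min(
            bridge(small, large[:j] + large[j + 1 :]) for j in range(len(large))
        )

    best = None
    for ra in _readings(A, expected):
        for rb in _readings(B, expected):
            small, large = (ra, rb) if len(ra) <= len(rb) else (rb, ra)
            cost = bridge(small, large)
            if best is None or cost < best:
                best = cost
    return best


# ---------------------------------------------------------------------------
# Fisher's exact test by full hypergeometric enumeration


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable than the
    observed table (relative tie gate 1 + 1e-7)."""
    n1, n2 = a + b, c + d
    n = n1 + n2
    k = a + c  # first-column margin
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    logp = np.array(
        [
            _log_comb(n1, x) + _log_comb(n2, k - x) - _log_comb(n, k)
            for x in support
        ]
    )
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    observed = pmf[a - lo]
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


# ---------------------------------------------------------------------------
# Expected parsimony-visible mutation rate under the stepwise walk


@functools.lru_cache(maxsize=None)
def mean_abs_walk(k: int) -> float:
    """E|W_k| for a simple symmetric +/-1 random walk after k steps."""
    return sum(comb(k, j) * abs(k - 2 * j) for j in range(k + 1)) / 2.0**k


@functools.lru_cache(maxsize=None)
def _expected_inferred_events(m: int, mu: float, copies: int) -> float:
    """E[parsimony-inferred step events] between two men separated by m
    meioses at one locus: mutations K ~ Bin(m, mu); each is a +/-1 step
    on one of `copies` copies; parsimony sees the per-copy |net| sums."""
    total = 0.0
    for k in range(m + 1):
        pk = comb(m, k) * mu**k * (1 - mu) ** (m - k)
        if copies == 1:
            e = mean_abs_walk(k)
        else:
            e = sum(
                comb(k, j) / 2.0**k * (mean_abs_walk(j) + mean_abs_walk(k - j))
                for j in range(k + 1)
            )
        total += pk * e
    return total


def expected_parsimony_rate(
    mu_step: float,
    meioses_counts: dict[int, int],
    copies: int = 1,
    p_dupdel: float = 0.0,
) -> float:
    """Expected estimated rate mu_hat = E[x]/N when parsimony counting is
    applied to stepwise-walk pairs (cancelling back/parallel mutations
    are invisible).  Copy-number events each surface as one event."""
    total, N = 0.0, 0
    for m, n_pairs in meioses_counts.items():
        N += m * n_pairs
        e = _expected_inferred_events(m, mu_step, copies)
        if copies == 2:
            e += m * p_dupdel
        total += n_pairs * e
    return total / N


def no_mutation_probability(panel_mu: list[float], m: int) -> float:
    """Closed-form P(zero mutations anywhere) for one pair at m meioses,
    ignoring parsimony collisions: prod_l (1 - mu_l)^m."""
    out = 1.0
    for mu in panel_mu:
        out *= (1.0 - mu) ** m
    return out
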