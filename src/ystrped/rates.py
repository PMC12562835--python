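"""Per-locus mutation-rate estimation and cross-study comparison.

The per-meiosis mutation rate at a locus is estimated as ``mu = x / N``
where ``x`` is the number of inferred mutations summed over pedigree
pairs and ``N`` the total number of meioses separating those pairs.
Because every pedigree contains exactly two men, pairwise and actual
meioses coincide and no transmission is double-counted.

Binomial 95% confidence intervals are provided by the exact
Clopper–Pearson method (beta quantiles) and the Wilson score interval.
Rates from different studies are compared with a two-sided Fisher's
exact test on the 2x2 table of mutations vs non-mutated meioses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .counting import PairComparison
from .model import LocusSpec

__all__ = [
    "RateEstimate",
    "RateComparison",
    "ci_clopper_pearson",
    "ci_wilson",
    "estimate_rates",
    "rates_from_counts",
    "compare_rates",
    "reconstruct_count",
    "round_half_up",
]

CI_METHODS = ("clopper_pearson", "wilson")


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Decimal round-half-up (0.0005 -> 0.001), as rate tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def _check_counts(x: int, n: int, alpha: float) -> None:
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, N], got x={x}, N={n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


def ci_clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval.

    Bounds are beta-distribution quantiles; x = 0 pins the lower bound at
    0 and x = N pins the upper bound at 1.
    """
    _check_counts(x, n, alpha)
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def ci_wilson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval; always within [0, 1] and containing x/N."""
    _check_counts(x, n, alpha)
    z = float(stats.norm.ppf(1 - alpha / 2))
    p = x / n
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = (p + z2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


_CI_FUNCS = {"clopper_pearson": ci_clopper_pearson, "wilson": ci_wilson}


@dataclass(frozen=True)
class RateEstimate:
    """Per-locus mutation-rate estimate with a binomial confidence interval."""

    locus: str
    x: int
    N: int
    mu_hat: float
    ci_low: float
    ci_high: float
    method: str = "clopper_pearson"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mu_hat <= self.ci_high:
            raise ValueError(f"{self.locus}: interval does not contain mu_hat")

    @property
    def mu_rounded(self) -> float:
        return round_half_up(self.mu_hat, 3)

    @property
    def ci_rounded(self) -> tuple[float, float]:
        return round_half_up(self.ci_low, 3), round_half_up(self.ci_high, 3)


@dataclass(frozen=True)
class RateComparison:
    """Two-sided Fisher's exact comparison of one locus across two studies."""

    locus: str
    x1: int
    N1: int
    x2: int
    N2: int
    p_value: float
    approximate: bool = False


def _estimate(locus: str, x: int, n: int, method: str, alpha: float) -> RateEstimate:
    if method not in _CI_FUNCS:
        raise ValueError(f"unknown CI method {method!r}; expected one of {CI_METHODS}")
    low, high = _CI_FUNCS[method](x, n, alpha)
    return RateEstimate(locus, x, n, x / n, low, high, method, alpha)


def estimate_rates(
    comparisons: Iterable[PairComparison],
    panel: Sequence[LocusSpec],
    method: str = "clopper_pearson",
    alpha: float = 0.05,
) -> list[RateEstimate]:
    """Estimate per-locus rates from filtered pair comparisons.

    x sums every inferred event at the locus (each decomposed step and
    each duplication/deletion/complex event is one mutation); N sums the
    pairs' meioses and is identical across loci.
    """
    comparisons = list(comparisons)
    N = sum(c.pair.meioses for c in comparisons)
    if N == 0:
        raise ValueError("no meioses: empty comparison list")
    counts = {spec.name: 0 for spec in panel}
    for comp in comparisons:
        for event in comp.events:
            if event.locus not in counts:
                raise ValueError(f"event at locus {event.locus!r} not in panel")
            counts[event.locus] += 1
    return [_estimate(spec.name, counts[spec.name], N, method, alpha) for spec in panel]


def rates_from_counts(
    counts: Mapping[str, int],
    total_meioses: int,
    method: str = "clopper_pearson",
    alpha: float = 0.05,
) -> list[RateEstimate]:
    """Counts-only mode: estimates straight from per-locus (x, N) counts,
    for published tables where raw genotypes are unavailable."""
    return [
        _estimate(locus, x, total_meioses, method, alpha)
        for locus, x in counts.items()
    ]


def compare_rates(
    x1: int, N1: int, x2: int, N2: int, locus: str = "", approximate: bool = False
) -> RateComparison:
    """Two-sided Fisher's exact test on [[x1, N1-x1], [x2, N2-x2]].

    The two-sided p-value sums hypergeometric probabilities of all tables
    (with fixed margins) no more probable than the observed one.  Set
    ``approximate=True`` when a reference study's count was reconstructed
    from a printed rate rather than taken from its own report.
    """
    for x, n in ((x1, N1), (x2, N2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError(f"invalid counts x={x}, N={n}")
    table = [[x1, N1 - x1], [x2, N2 - x2]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return RateComparison(locus, x1, N1, x2, N2, float(min(p, 1.0)), approximate)


def reconstruct_count(rate: float, total_meioses: int) -> int:
    """Reconstruct an integer mutation count from a printed rate.

    Published comparison tables often print only rates; ``x = round(rate
    * N)`` recovers the count up to the printing precision.  P-values
    computed from reconstructed counts are approximate and flagged so.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    return int(round_half_up(rate * total_meioses, 0))
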