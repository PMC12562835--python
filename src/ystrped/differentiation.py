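"""Male-relative differentiation rates and discordance distributions.

A related male pair is *differentiated* when its two haplotypes show at
least one allelic difference — any locus with >= 1 inferred mutation
event, including copy-number and complex events.  The differentiation
rate at a given meioses separation is the proportion of pairs at that
separation that are differentiated; exact Clopper–Pearson intervals
quantify its uncertainty.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .counting import PairComparison
from .model import Haplotype, LocusSpec
from .rates import ci_clopper_pearson, round_half_up

__all__ = [
    "DifferentiationSummary",
    "DiscordanceDistribution",
    "differentiation_rate",
    "discordance_distribution",
    "unique_haplotype_count",
]

Stratum = int | tuple[int, int] | str


@dataclass(frozen=True)
class DifferentiationSummary:
    """Differentiation within one meioses stratum.

    ``stratum`` is a single meioses value (``"8"``), an inclusive range
    (``"4-13"``), or ``"all"``.  ``rate`` is None for an empty stratum.
    """

    stratum: str
    n_pairs: int
    n_differentiated: int
    rate: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def percent(self) -> float | None:
        """Rate as a percentage rounded half-up to one decimal place."""
        if self.rate is None:
            return None
        return round_half_up(100.0 * self.rate, 1)


@dataclass(frozen=True)
class DiscordanceDistribution:
    """Histogram of per-pair mutation counts and per-locus pair counts."""

    counts: dict[int, int]
    per_locus: dict[str, int]

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def n_differentiated(self) -> int:
        return self.n_pairs - self.counts.get(0, 0)


def _stratum_label(stratum: Stratum) -> str:
    if isinstance(stratum, tuple):
        lo, hi = stratum
        return f"{lo}-{hi}"
    return str(stratum)


def _in_stratum(meioses: int, stratum: Stratum) -> bool:
    if stratum == "all":
        return True
    if isinstance(stratum, tuple):
        lo, hi = stratum
        return lo <= meioses <= hi
    return meioses == int(stratum)


def _summarise(
    comparisons: Sequence[PairComparison], stratum: Stratum, alpha: float
) -> DifferentiationSummary:
    members = [c for c in comparisons if _in_stratum(c.pair.meioses, stratum)]
    n = len(members)
    label = _stratum_label(stratum)
    if n == 0:
        return DifferentiationSummary(label, 0, 0, None, None, None)
    k = sum(1 for c in members if c.loci_discordant)
    low, high = ci_clopper_pearson(k, n, alpha)
    return DifferentiationSummary(label, n, k, k / n, low, high)


def differentiation_rate(
    comparisons: Iterable[PairComparison],
    strata: Sequence[Stratum] | None = None,
    alpha: float = 0.05,
) -> list[DifferentiationSummary]:
    """Differentiation per stratum plus an overall ``"all"`` row.

    Default strata are the individual meioses values present in the
    data; pass explicit values and/or inclusive ``(lo, hi)`` ranges to
    override.  The ``"all"`` row is always appended.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("no comparisons")
    if strata is None:
        strata = sorted({c.pair.meioses for c in comparisons})
    out = [_summarise(comparisons, s, alpha) for s in strata]
    out.append(_summarise(comparisons, "all", alpha))
    return out


def discordance_distribution(
    comparisons: Iterable[PairComparison],
) -> DiscordanceDistribution:
    """Histogram over per-pair total mutation counts, plus for each locus
    the number of pairs with at least one event there."""
    counts: Counter[int] = Counter()
    per_locus: Counter[str] = Counter()
    for comp in comparisons:
        counts[comp.total_mutations] += 1
        for locus in comp.loci_discordant:
            per_locus[locus] += 1
    return DiscordanceDistribution(dict(counts), dict(per_locus))


def unique_haplotype_count(
    haplotypes: Iterable[Haplotype], panel: Sequence[LocusSpec]
) -> int:
    """Number of distinct full-panel haplotypes (per-locus multiset
    equality).  With one man per family this is the numerator of the
    haplotype discrimination capacity."""
    return len({hap.key(panel) for hap in haplotypes})
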