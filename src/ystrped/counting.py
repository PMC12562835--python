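"""Parsimony mutation counting between the haplotypes of a pedigree pair.

Given two multi-locus Y-STR genotypes separated by an arbitrary number of
meioses, infer the minimum-mutation explanation of their per-locus
differences:

* a k-repeat difference between same-nomenclature alleles is decomposed
  into k single-step events (one repeat gained or lost per event);
* a copy-number change at a locus costs exactly one duplication or
  deletion event, with the gained/lost copy chosen to minimise the
  residual step cost;
* a locus-wide null (``NEG``) against a called allele is one deletion
  event; shared nulls are a shared state and cost nothing;
* a microvariant mismatch (e.g. 16 vs 16.2) is a single "complex" event —
  repeat steps cannot interconvert nomenclatures, so no step decomposition
  is defined and one event is the parsimony-minimal reading;
* a single displayed allele at an expected two-copy locus may hide a
  homoallelic pair; both readings are costed and the cheaper wins, with
  ties resolved toward the homoallelic (event-free) reading.

Because zero observed difference is explained by zero events, parallel
and back mutations along the unobserved lineage are knowingly uncounted;
the inferred count is a lower bound on the true number of events.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import Allele, Haplotype, LocusSpec, PedigreePair

__all__ = [
    "MutationEvent",
    "PairComparison",
    "count_single_copy",
    "count_multi_copy",
    "count_locus",
    "compare_pair",
    "filter_pairs",
    "DEFAULT_MAX_MUTATIONS",
]

logger = logging.getLogger(__name__)

SINGLE_STEP = "single_step"
DUPLICATION = "duplication"
DELETION = "deletion"
COMPLEX = "complex"

DEFAULT_MAX_MUTATIONS = 15
_MAX_OBSERVED_COPIES = 4

_KIND_ORDER = {SINGLE_STEP: 0, DUPLICATION: 1, DELETION: 2, COMPLEX: 3}


@dataclass(frozen=True)
class MutationEvent:
    """One inferred mutation.  Every event counts as one mutation; a
    decomposed k-step difference is emitted as k single-step events."""

    locus: str
    kind: str
    steps: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.kind == SINGLE_STEP and self.steps != 1:
            raise ValueError("single-step events carry exactly one step")


@dataclass(frozen=True)
class PairComparison:
    """Inferred events for one pedigree pair."""

    pair: PedigreePair
    events: tuple[MutationEvent, ...]
    loci_discordant: frozenset[str]

    @property
    def total_mutations(self) -> int:
        return len(self.events)

    def events_at(self, locus: str) -> list[MutationEvent]:
        return [e for e in self.events if e.locus == locus]


def _allele_events(locus: str, a: Allele, b: Allele) -> list[MutationEvent]:
    """Events explaining one matched allele pair (neither null)."""
    if a.frac != b.frac:
        return [MutationEvent(locus, COMPLEX)]
    k = abs(a.whole - b.whole)
    return [MutationEvent(locus, SINGLE_STEP)] * k


def count_single_copy(
    locus: LocusSpec | str, a: Allele, b: Allele
) -> list[MutationEvent]:
    """Minimum-mutation explanation for a single-copy locus.

    A k-repeat shift between same-nomenclature alleles is k single-step
    events; exactly one null call is a deletion; a shared null is a shared
    state (zero events); a microvariant mismatch is one complex event.
    """
    name = locus.name if isinstance(locus, LocusSpec) else locus
    if a.is_null and b.is_null:
        return []
    if a.is_null or b.is_null:
        return [MutationEvent(name, DELETION)]
    return _allele_events(name, a, b)


def _interpretations(
    multiset: tuple[Allele, ...], expected: int
) -> set[tuple[Allele, ...]]:
    """All readings of an observed multiset: as-is, plus homoallelic
    expansions (hidden same-size copies) up to the expected copy number."""
    out = {multiset}
    frontier = [multiset]
    while frontier:
        cur = frontier.pop()
        if len(cur) < expected:
            for allele in set(cur):
                nxt = tuple(sorted(cur + (allele,)))
                if nxt not in out:
                    out.add(nxt)
                    frontier.append(nxt)
    return out


def _event_sort_key(e: MutationEvent) -> tuple:
    return (_KIND_ORDER[e.kind], e.steps)


def _best_matching(
    name: str, left: Sequence[Allele], right: Sequence[Allele]
) -> tuple[int, int, list[MutationEvent]]:
    """Min-cost perfect matching between equal-size allele multisets.

    Returns (cost, n_complex, events).  Sizes are at most 4, so all
    bijections are enumerated directly; ties prefer step decompositions
    over complex events, then the lexicographically smallest event list.
    """
    best: tuple | None = None
    for perm in itertools.permutations(range(len(right))):
        events: list[MutationEvent] = []
        for i, j in enumerate(perm):
            events.extend(_allele_events(name, left[i], right[j]))
        events.sort(key=_event_sort_key)
        n_complex = sum(1 for e in events if e.kind == COMPLEX)
        key = (len(events), n_complex, tuple(_event_sort_key(e) for e in events))
        if best is None or key < best[0]:
            best = (key, events)
    assert best is not None
    key, events = best
    return key[0], key[1], events


def _copy_event_kinds(n_small: int, n_large: int, expected: int) -> list[str]:
    """Kinds of the copy-number events bridging sizes n_small -> n_large.

    Copies above the expected number are duplications; copies missing
    below it are deletions.  Each costs one mutation.
    """
    return [
        DUPLICATION if c >= expected else DELETION for c in range(n_small, n_large)
    ]


def count_multi_copy(
    locus: LocusSpec,
    A: Iterable[Allele],
    B: Iterable[Allele],
) -> list[MutationEvent]:
    """Minimum-mutation explanation between two allele multisets.

    Enumerates every reading of the observed multisets (homoallelic
    hidden copies, choice of gained/lost copy for copy-number changes)
    and returns the cheapest event list.  Ties are broken toward fewer
    copy-number events (homoallelic reading), then toward minimal
    residual step cost, then toward the smaller gained/lost allele.
    """
    A = tuple(sorted(A))
    B = tuple(sorted(B))
    if not A or not B:
        raise ValueError(f"{locus.name}: empty allele multiset")
    if len(A) > _MAX_OBSERVED_COPIES or len(B) > _MAX_OBSERVED_COPIES:
        raise ValueError(
            f"{locus.name}: more than {_MAX_OBSERVED_COPIES} copies observed"
        )
    a_null, b_null = A[0].is_null, B[0].is_null
    if a_null and b_null:
        return []
    if a_null or b_null:
        return [MutationEvent(locus.name, DELETION)]
    if A == B:
        return []

    expected = locus.expected_copies
    best: tuple | None = None
    for TA in _interpretations(A, expected):
        for TB in _interpretations(B, expected):
            small, large = (TA, TB) if len(TA) <= len(TB) else (TB, TA)
            d = len(large) - len(small)
            if d == 0:
                cost, n_complex, events = _best_matching(locus.name, TA, TB)
                key = (cost, 0, n_complex, (), tuple(_event_sort_key(e) for e in events))
                cand = (key, events)
                if best is None or key < best[0]:
                    best = cand
                continue
            kinds = _copy_event_kinds(len(small), len(large), expected)
            for removed_idx in itertools.combinations(range(len(large)), d):
                residual = [
                    large[i] for i in range(len(large)) if i not in removed_idx
                ]
                cost_m, n_complex, match_events = _best_matching(
                    locus.name, small, residual
                )
                events = [MutationEvent(locus.name, k) for k in kinds] + match_events
                removed_key = tuple(
                    (large[i].whole, large[i].frac) for i in removed_idx
                )
                key = (
                    cost_m + d,
                    d,
                    n_complex,
                    removed_key,
                    tuple(_event_sort_key(e) for e in events),
                )
                if best is None or key < best[0]:
                    best = (key, events)
    assert best is not None
    return best[1]


def count_locus(
    locus: LocusSpec, A: Iterable[Allele], B: Iterable[Allele]
) -> list[MutationEvent]:
    """Dispatch on copy number: plain single-copy comparison when both men
    show one allele at an expected single-copy locus, multiset parsimony
    otherwise (covers duplications observed at nominally single-copy
    markers)."""
    A = tuple(sorted(A))
    B = tuple(sorted(B))
    if locus.expected_copies == 1 and len(A) == 1 and len(B) == 1:
        return count_single_copy(locus, A[0], B[0])
    return count_multi_copy(locus, A, B)


def compare_pair(
    pair: PedigreePair, panel: Sequence[LocusSpec]
) -> PairComparison:
    """Concatenate per-locus minimum-mutation event lists for one pair."""
    for hap in (pair.hap1, pair.hap2):
        if not hap.covers(panel):
            missing = [s.name for s in panel if s.name not in hap.calls]
            raise ValueError(
                f"pair {pair.family_id}: sample {hap.sample_id} lacks loci {missing}"
            )
    events: list[MutationEvent] = []
    for spec in panel:
        A = pair.hap1.calls[spec.name]
        B = pair.hap2.calls[spec.name]
        if A == B:
            continue
        try:
            events.extend(count_locus(spec, A, B))
        except ValueError as exc:
            raise ValueError(f"pair {pair.family_id}, locus {spec.name}: {exc}") from exc
    return PairComparison(
        pair=pair,
        events=tuple(events),
        loci_discordant=frozenset(e.locus for e in events),
    )


def filter_pairs(
    comparisons: Iterable[PairComparison],
    max_mutations: int = DEFAULT_MAX_MUTATIONS,
) -> tuple[list[PairComparison], list[PairComparison]]:
    """Split comparisons into (kept, excluded) by total mutation count.

    Pairs with more than ``max_mutations`` inferred mutations show too
    much variation to be plausibly patrilineally related and are excluded
    from rate estimation (the boundary count itself is kept).
    """
    kept, excluded = [], []
    for comp in comparisons:
        if comp.total_mutations > max_mutations:
            logger.info(
                "excluding pair %s: %d mutations (> %d)",
                comp.pair.family_id,
                comp.total_mutations,
                max_mutations,
            )
            excluded.append(comp)
        else:
            kept.append(comp)
    return kept, excluded
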