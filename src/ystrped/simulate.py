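"""Seeded simulator of two-man pedigrees under a stepwise mutation model.

Each simulated pedigree places a founder haplotype at the apex and lets
two patrilineal branches of total length ``m`` meioses descend to the
two sampled men (branch lengths drawn uniformly over compositions
``m1 + m2 = m``).  Per meiosis and locus a mutation occurs with the
locus's per-meiosis probability ``mu``; a mutation moves one allele copy
by one repeat unit up or down with equal probability (optionally more
under a geometric multi-step law).  Multi-copy loci can additionally
gain a copy (duplicating an existing allele, offset by 0 or +/-1 repeat)
or lose a uniformly chosen copy at a small per-meiosis probability.

Every simulated event is recorded in a truth log, so parsimony-inferred
counts can be checked against the generative truth: with single-step
mutations only, the inferred count per pair and locus can never exceed
the true count (net drift bounds event number from below).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import PairRef
from .model import Allele, Haplotype, LocusSpec, PedigreePair
from .panel import MULTI_COPY_LOCI, STUDY_TOTAL_MEIOSES, yfiler_plus_panel

__all__ = [
    "SimConfig",
    "TruthEvent",
    "TruthLog",
    "SimResult",
    "simulate_pairs",
    "study_like_config",
    "STUDY_MEIOSES_COUNTS",
    "DEFAULT_P_DUPDEL",
]

# Per-meiosis copy-number event probability at multi-copy loci; scaled to
# the handful of gain/loss events seen per ~1576 meioses in deep-pedigree
# panels of this size.
DEFAULT_P_DUPDEL = 2 / STUDY_TOTAL_MEIOSES

# Fixed study-like meioses multiset: 183 pairs over 4..16 meioses summing
# to exactly 1576 (mean 8.61), right-skewed and unimodal.
STUDY_MEIOSES_COUNTS: dict[int, int] = {
    4: 13, 5: 14, 6: 19, 7: 23, 8: 25, 9: 24, 10: 19,
    11: 15, 12: 12, 13: 9, 14: 5, 15: 3, 16: 2,
}

_MAX_COPIES = 4


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the pedigree simulator.

    ``meioses`` is either an explicit per-pair list (length ``n_pairs``)
    or a mapping meioses -> probability.  ``p_multistep`` is the chance a
    mutation event moves more than one repeat; extra step counts follow a
    geometric law with parameter ``step_size_p``.  ``p_dupdel`` applies
    per meiosis at expected two-copy loci only.
    """

    panel: tuple[LocusSpec, ...]
    n_pairs: int = 183
    meioses: Sequence[int] | Mapping[int, float] = field(
        default_factory=lambda: dict(STUDY_MEIOSES_COUNTS)
    )
    p_multistep: float = 0.0
    step_size_p: float = 0.5
    p_dupdel: float = DEFAULT_P_DUPDEL

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for p in (self.p_multistep, self.p_dupdel):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0.0 < self.step_size_p <= 1.0:
            raise ValueError("step_size_p must be in (0, 1]")
        if isinstance(self.meioses, Mapping):
            if any(m < 1 for m in self.meioses):
                raise ValueError("meioses values must be >= 1")
        elif len(self.meioses) != self.n_pairs:
            raise ValueError("explicit meioses list must have n_pairs entries")


@dataclass(frozen=True)
class TruthEvent:
    """One simulated mutation: pair, locus, branch (1 or 2), meiosis index
    within the branch, kind ('step' | 'dup' | 'del'), and signed repeat
    delta (0 for dup/del)."""

    family_id: str
    locus: str
    branch: int
    meiosis: int
    kind: str
    delta: int


@dataclass
class TruthLog:
    """All simulated events, with per-pair/locus count accessors."""

    events: list[TruthEvent] = field(default_factory=list)

    def count(self, family_id: str, locus: str) -> int:
        return sum(
            1 for e in self.events if e.family_id == family_id and e.locus == locus
        )

    def counts_by_locus(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.locus] = out.get(e.locus, 0) + 1
        return out


@dataclass
class SimResult:
    haplotypes: list[Haplotype]
    pair_refs: list[PairRef]
    pairs: list[PedigreePair]
    truth: TruthLog
    seed: int


def _draw_meioses(config: SimConfig, rng: np.random.Generator) -> list[int]:
    if isinstance(config.meioses, Mapping):
        values = np.array(sorted(config.meioses), dtype=int)
        weights = np.array([config.meioses[int(v)] for v in values], dtype=float)
        total = weights.sum()
        if total <= 0:
            raise ValueError("meioses weights must sum to a positive value")
        if abs(total - config.n_pairs) < 1e-9 and np.allclose(weights, weights.round()):
            # Exact multiset of counts: lay it out deterministically.
            out = np.repeat(values, weights.round().astype(int)).tolist()
            rng.shuffle(out)
            return [int(m) for m in out]
        return [
            int(v) for v in rng.choice(values, size=config.n_pairs, p=weights / total)
        ]
    return [int(m) for m in config.meioses]


def _step_size(config: SimConfig, rng: np.random.Generator) -> int:
    if config.p_multistep > 0.0 and rng.random() < config.p_multistep:
        return 1 + int(rng.geometric(config.step_size_p))
    return 1


def _mutate_branch(
    alleles: list[Allele],
    spec: LocusSpec,
    n_meioses: int,
    config: SimConfig,
    rng: np.random.Generator,
    log: TruthLog,
    family_id: str,
    branch: int,
) -> list[Allele]:
    """Walk one locus down one branch, logging every event."""
    multi = spec.expected_copies == 2
    for meiosis in range(1, n_meioses + 1):
        if rng.random() < spec.mu:
            size = _step_size(config, rng)
            sign = 1 if rng.random() < 0.5 else -1
            idx = int(rng.integers(len(alleles))) if len(alleles) > 1 else 0
            a = alleles[idx]
            new_whole = a.whole + sign * size
            if new_whole < 1:
                new_whole = 2 - new_whole  # reflect at one repeat
            alleles[idx] = replace(a, whole=new_whole)
            log.events.append(
                TruthEvent(family_id, spec.name, branch, meiosis, "step", sign * size)
            )
        if multi and config.p_dupdel > 0.0 and rng.random() < config.p_dupdel:
            gain = rng.random() < 0.5
            if gain and len(alleles) < _MAX_COPIES:
                src = alleles[int(rng.integers(len(alleles)))]
                offset = int(rng.integers(-1, 2))
                new_whole = max(1, src.whole + offset)
                alleles.append(replace(src, whole=new_whole))
                log.events.append(
                    TruthEvent(family_id, spec.name, branch, meiosis, "dup", 0)
                )
            elif not gain and len(alleles) > 1:
                alleles.pop(int(rng.integers(len(alleles))))
                log.events.append(
                    TruthEvent(family_id, spec.name, branch, meiosis, "del", 0)
                )
        alleles.sort()
    return alleles


def _founder(spec: LocusSpec, rng: np.random.Generator) -> list[Allele]:
    lo, hi = spec.founder_range or (10, 20)
    n = spec.expected_copies
    return sorted(Allele(int(rng.integers(lo, hi + 1))) for _ in range(n))


def simulate_pairs(config: SimConfig, seed: int = 0) -> SimResult:
    """Simulate two-man pedigrees under the stepwise mutation model.

    Deterministic for a fixed seed.  Returns haplotypes, a pair manifest,
    joined pairs, and the truth log of every simulated event.
    """
    rng = np.random.default_rng(seed)
    meioses = _draw_meioses(config, rng)
    haplotypes: list[Haplotype] = []
    refs: list[PairRef] = []
    truth = TruthLog()
    for i, m in enumerate(meioses):
        family_id = f"SIM_{i + 1}"
        m1 = int(rng.integers(0, m + 1))  # uniform over compositions m1 + m2 = m
        m2 = m - m1
        calls1: dict[str, tuple[Allele, ...]] = {}
        calls2: dict[str, tuple[Allele, ...]] = {}
        for spec in config.panel:
            founder = _founder(spec, rng)
            a1 = _mutate_branch(
                list(founder), spec, m1, config, rng, truth, family_id, 1
            )
            a2 = _mutate_branch(
                list(founder), spec, m2, config, rng, truth, family_id, 2
            )
            calls1[spec.name] = tuple(a1)
            calls2[spec.name] = tuple(a2)
        s1, s2 = f"{family_id}_A", f"{family_id}_B"
        haplotypes.append(Haplotype(s1, calls1))
        haplotypes.append(Haplotype(s2, calls2))
        refs.append(PairRef(family_id, s1, s2, m))
    pairs = [
        PedigreePair(r.family_id, haplotypes[2 * i], haplotypes[2 * i + 1], r.meioses)
        for i, r in enumerate(refs)
    ]
    return SimResult(haplotypes, refs, pairs, truth, seed)


def study_like_config(
    p_dupdel: float = DEFAULT_P_DUPDEL,
    p_multistep: float = 0.0,
) -> SimConfig:
    """The study conditions: 183 pairs over 4–16 meioses summing to 1576,
    per-locus rates equal to the bundled study rates.

    At the two-copy loci the bundled rate counts copy-number events among
    the mutations, so the stepwise component is reduced by ``p_dupdel``
    to keep each locus's total per-meiosis event rate at the bundled
    value.
    """
    panel = []
    for spec in yfiler_plus_panel():
        if spec.name in MULTI_COPY_LOCI and p_dupdel > 0.0:
            panel.append(replace(spec, mu=max(0.0, spec.mu - p_dupdel)))
        else:
            panel.append(spec)
    return SimConfig(
        panel=tuple(panel),
        n_pairs=183,
        meioses=dict(STUDY_MEIOSES_COUNTS),
        p_multistep=p_multistep,
        p_dupdel=p_dupdel,
    )
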