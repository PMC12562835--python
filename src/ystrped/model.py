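"""Core domain types for Y-STR haplotype analysis.

A Y-STR genotype is a per-locus multiset of repeat-count alleles.  Alleles
may carry a partial-repeat microvariant (e.g. ``20.2`` = 20 full repeats
plus 2 bases) or be null (``NEG``, no amplification product).  Multi-copy
markers (DYS385, DYF387S1) report two copies per man; copy-number
mutations can push any marker above or below its expected copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Allele",
    "NULL_ALLELE",
    "LocusSpec",
    "Haplotype",
    "PedigreePair",
    "parse_allele",
]

_VALID_FRACTIONS = (0, 1, 2, 3)


@dataclass(frozen=True, order=True)
class Allele:
    """A single Y-STR allele.

    Parameters
    ----------
    whole:
        Number of full repeat units (positive for a called allele).
    frac:
        Partial-repeat microvariant digit in {0, 1, 2, 3}; ``20.2`` is
        ``Allele(20, 2)``.
    is_null:
        True for a ``NEG`` call (no amplification product).  Null alleles
        carry no repeat count.
    """

    whole: int
    frac: int = 0
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.is_null:
            if self.whole != 0 or self.frac != 0:
                raise ValueError("null allele carries no repeat count")
            return
        if self.whole <= 0:
            raise ValueError(f"allele repeat count must be positive, got {self.whole}")
        if self.frac not in _VALID_FRACTIONS:
            raise ValueError(
                f"microvariant digit must be one of {_VALID_FRACTIONS}, got {self.frac}"
            )

    @property
    def repeats(self) -> float | None:
        """Decimal repeat count, or None for a null allele."""
        if self.is_null:
            return None
        return self.whole + self.frac / 10.0

    @property
    def label(self) -> str:
        """The allele as written in a genotype table (``15``, ``20.2``, ``NEG``)."""
        if self.is_null:
            return "NEG"
        if self.frac:
            return f"{self.whole}.{self.frac}"
        return str(self.whole)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


NULL_ALLELE = Allele(0, 0, is_null=True)


def parse_allele(token: str) -> Allele:
    """Parse one allele token (``"15"``, ``"15.0"``, ``"20.2"``, ``"NEG"``).

    ``15`` and ``15.0`` map to the same allele.  Raises ``ValueError`` on
    anything else (letters, negative or zero repeats, fraction digits
    outside STR nomenclature).
    """
    token = token.strip()
    if not token:
        raise ValueError("empty allele token")
    if token.upper() == "NEG":
        return NULL_ALLELE
    whole_s, _, frac_s = token.partition(".")
    try:
        whole = int(whole_s)
        frac = int(frac_s) if frac_s else 0
    except ValueError as exc:
        raise ValueError(f"unparseable allele token {token!r}") from exc
    return Allele(whole, frac)


@dataclass(frozen=True)
class LocusSpec:
    """A Y-STR marker: identity, expected copy number, per-meiosis rate.

    ``mu`` is the marker's per-meiosis mutation probability — a simulation
    truth value or a reference estimate, depending on context.
    """

    name: str
    expected_copies: int = 1
    mu: float = 0.0
    founder_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.expected_copies not in (1, 2):
            raise ValueError("expected_copies must be 1 or 2")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if self.founder_range is not None:
            lo, hi = self.founder_range
            if not (0 < lo <= hi):
                raise ValueError(f"invalid founder range {self.founder_range}")


def _canonical_calls(
    calls: Mapping[str, Iterable[Allele]],
) -> dict[str, tuple[Allele, ...]]:
    out: dict[str, tuple[Allele, ...]] = {}
    for locus, alleles in calls.items():
        multiset = tuple(sorted(alleles))
        if not multiset:
            raise ValueError(f"locus {locus}: empty allele multiset")
        if any(a.is_null for a in multiset) and len(multiset) > 1:
            raise ValueError(f"locus {locus}: null call must be the only allele")
        out[locus] = multiset
    return out


@dataclass(frozen=True)
class Haplotype:
    """One man's multi-locus Y-STR genotype.

    ``calls`` maps locus name to a canonically sorted allele multiset.  A
    locus-wide null is the one-element multiset ``(NULL_ALLELE,)``.  A
    single displayed allele at an expected two-copy locus is stored as a
    one-element multiset; whether it hides a homoallelic pair or a deleted
    copy is decided downstream by the mutation counter.
    """

    sample_id: str
    calls: Mapping[str, tuple[Allele, ...]] = field(compare=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "calls", _canonical_calls(self.calls))

    def covers(self, panel: Iterable[LocusSpec]) -> bool:
        return all(spec.name in self.calls for spec in panel)

    def key(self, panel: Iterable[LocusSpec]) -> tuple:
        """Hashable full-panel genotype key (multiset equality per locus)."""
        return tuple(self.calls[spec.name] for spec in panel)


@dataclass(frozen=True)
class PedigreePair:
    """Two sampled males joined through a known patrilineal pedigree.

    ``meioses`` is the number of germline transmissions along the
    patrilineal path connecting them (first cousins = 4).  Study-like data
    ranges over 4–16, but any value >= 1 is accepted.
    """

    family_id: str
    hap1: Haplotype
    hap2: Haplotype
    meioses: int

    def __post_init__(self) -> None:
        if self.meioses < 1:
            raise ValueError(f"pair {self.family_id}: meioses must be >= 1")
        if self.hap1.sample_id == self.hap2.sample_id:
            raise ValueError(
                f"pair {self.family_id}: the two samples must be distinct"
            )
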