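from __future__ import annotations

import pytest

from ystrped.model import Allele, Haplotype, LocusSpec, PedigreePair, parse_allele
from ystrped.panel import yfiler_plus_panel


@pytest.fixture(scope="session")
def panel() -> list[LocusSpec]:
    return yfiler_plus_panel()


def make_haplotype(sample_id: str, panel, overrides: dict[str, str] | None = None) -> Haplotype:
    """Build a full-panel haplotype from a baseline (low end of each
    founder range, two copies at two-copy loci) with per-locus string
    overrides like ``{"DYS627": "20.2", "DYS385": "13,17"}``."""
    overrides = overrides or {}
    calls = {}
    for spec in panel:
        if spec.name in overrides:
            calls[spec.name] = tuple(
                parse_allele(t) for t in overrides[spec.name].split(",")
            )
        else:
            lo, hi = spec.founder_range or (10, 20)
            base = (lo + hi) // 2
            if spec.expected_copies == 2:
                calls[spec.name] = (Allele(base), Allele(base + 2))
            else:
                calls[spec.name] = (Allele(base),)
    return Haplotype(sample_id, calls)


def make_pair(panel, family_id="F1", meioses=8, overrides1=None, overrides2=None):
    h1 = make_haplotype(f"{family_id}_A", panel, overrides1)
    h2 = make_haplotype(f"{family_id}_B", panel, overrides2)
    return PedigreePair(family_id, h1, h2, meioses)
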