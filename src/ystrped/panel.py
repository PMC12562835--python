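"""The Yfiler Plus marker panel and bundled study counts.

The panel covers 27 Y-chromosomal STRs reported as 25 markers: DYS385 and
DYF387S1 each amplify two Y-chromosome copies and are reported once as an
allele multiset.  Six markers are rapidly mutating (RM) Y-STRs with
per-meiosis rates around 1e-2.

``STUDY_MUTATION_COUNTS`` holds the published per-marker mutation counts
observed across ``STUDY_TOTAL_MEIOSES`` = 1576 meioses (183 two-man
pedigrees separated by 4–16 meioses); these counts are the package's
reference rates (``mu = x / 1576``) and the defaults for the pedigree
simulator.  Founder allele ranges are approximate published Yfiler Plus
allele ranges and are used only to draw simulation founders.
"""

from __future__ import annotations

from .model import LocusSpec

__all__ = [
    "STUDY_TOTAL_MEIOSES",
    "STUDY_MUTATION_COUNTS",
    "MULTI_COPY_LOCI",
    "RM_LOCI",
    "PANEL_ORDER",
    "yfiler_plus_panel",
]

STUDY_TOTAL_MEIOSES = 1576

# Per-marker mutation counts over 1576 meioses (includes copy-number events).
STUDY_MUTATION_COUNTS: dict[str, int] = {
    "DYF387S1": 13,
    "DYS19": 0,
    "DYS385": 6,
    "DYS389I": 0,
    "DYS389II": 1,
    "DYS390": 4,
    "DYS391": 2,
    "DYS392": 0,
    "DYS393": 1,
    "DYS437": 2,
    "DYS438": 0,
    "DYS439": 12,
    "DYS448": 1,
    "DYS449": 6,
    "DYS456": 6,
    "DYS458": 11,
    "DYS460": 8,
    "DYS481": 8,
    "DYS518": 18,
    "DYS533": 5,
    "DYS570": 5,
    "DYS576": 20,
    "DYS627": 21,
    "DYS635": 5,
    "YGATAH4": 6,
}

MULTI_COPY_LOCI = frozenset({"DYS385", "DYF387S1"})

# Rapidly mutating Y-STRs in the Yfiler Plus panel.
RM_LOCI = frozenset({"DYF387S1", "DYS449", "DYS518", "DYS570", "DYS576", "DYS627"})

# Approximate published allele ranges (full repeats) for founder sampling.
_FOUNDER_RANGES: dict[str, tuple[int, int]] = {
    "DYF387S1": (33, 42),
    "DYS19": (10, 19),
    "DYS385": (10, 22),
    "DYS389I": (10, 15),
    "DYS389II": (26, 32),
    "DYS390": (19, 26),
    "DYS391": (7, 13),
    "DYS392": (7, 17),
    "DYS393": (10, 16),
    "DYS437": (13, 17),
    "DYS438": (8, 13),
    "DYS439": (9, 14),
    "DYS448": (17, 23),
    "DYS449": (25, 35),
    "DYS456": (13, 18),
    "DYS458": (14, 20),
    "DYS460": (8, 12),
    "DYS481": (20, 30),
    "DYS518": (35, 45),
    "DYS533": (9, 14),
    "DYS570": (14, 21),
    "DYS576": (14, 21),
    "DYS627": (16, 25),
    "DYS635": (19, 25),
    "YGATAH4": (10, 13),
}

PANEL_ORDER: tuple[str, ...] = tuple(sorted(STUDY_MUTATION_COUNTS))


def yfiler_plus_panel(
    mu: dict[str, float] | None = None,
    total_meioses: int = STUDY_TOTAL_MEIOSES,
) -> list[LocusSpec]:
    """Build the Yfiler Plus panel as a list of :class:`LocusSpec`.

    By default each marker's ``mu`` is the bundled study rate
    ``x / total_meioses``; pass ``mu`` to override per-marker rates
    (markers not named keep the default).
    """
    overrides = mu or {}
    panel = []
    for name in PANEL_ORDER:
        rate = overrides.get(name, STUDY_MUTATION_COUNTS[name] / total_meioses)
        panel.append(
            LocusSpec(
                name=name,
                expected_copies=2 if name in MULTI_COPY_LOCI else 1,
                mu=rate,
                founder_range=_FOUNDER_RANGES[name],
            )
        )
    return panel
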