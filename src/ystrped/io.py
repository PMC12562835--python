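"""Readers and writers for haplotype tables and pair manifests.

Haplotype tables are GeneMapper-export-like: one row per sample, a
``sample_id`` column, then one column per marker.  Multi-copy cells list
alleles separated by commas (quoted in CSV); ``NEG`` marks a locus-wide
null.  Pair manifests have columns ``family_id, sample1, sample2,
meioses``.  Dialect (tab vs comma) is auto-detected from the file
extension and can be overridden.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .model import Allele, Haplotype, LocusSpec, PedigreePair, parse_allele

__all__ = [
    "PairRef",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_pair_manifest",
    "write_pair_manifest",
    "join_pairs",
]

SAMPLE_COLUMN = "sample_id"
MULTI_ALLELE_SEP = ","


@dataclass(frozen=True)
class PairRef:
    """A pair-manifest row: pedigree ID, two sample IDs, meioses count."""

    family_id: str
    sample1: str
    sample2: str
    meioses: int


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_cell(cell: str, *, row: int, column: str) -> tuple[Allele, ...]:
    tokens = [t for t in cell.split(MULTI_ALLELE_SEP)]
    try:
        alleles = tuple(parse_allele(t) for t in tokens)
    except ValueError as exc:
        raise ValueError(f"row {row}, column {column!r}: {exc}") from exc
    if len(alleles) > 1 and any(a.is_null for a in alleles):
        raise ValueError(f"row {row}, column {column!r}: NEG must stand alone")
    return alleles


def read_haplotype_table(
    path: str | Path,
    panel: Sequence[LocusSpec],
    delimiter: str | None = None,
) -> list[Haplotype]:
    """Read a haplotype table covering every panel locus.

    Raises ``ValueError`` for unknown locus columns, missing panel
    columns, unparseable allele tokens, missing cells, or duplicate
    sample IDs: the analysis excludes incomplete genotypes, so partial
    rows are a hard error rather than silently dropped.
    """
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    panel_names = [spec.name for spec in panel]
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        if SAMPLE_COLUMN not in header:
            raise ValueError(f"haplotype table must have a {SAMPLE_COLUMN!r} column")
        unknown = [c for c in header if c != SAMPLE_COLUMN and c not in panel_names]
        if unknown:
            raise ValueError(f"unknown locus column(s): {', '.join(unknown)}")
        missing = [n for n in panel_names if n not in header]
        if missing:
            raise ValueError(f"missing panel column(s): {', '.join(missing)}")
        haplotypes: list[Haplotype] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            sample_id = (row[SAMPLE_COLUMN] or "").strip()
            if not sample_id:
                raise ValueError(f"row {i}: empty {SAMPLE_COLUMN}")
            if sample_id in seen:
                raise ValueError(f"row {i}: duplicate sample id {sample_id!r}")
            seen.add(sample_id)
            calls = {}
            for name in panel_names:
                cell = (row.get(name) or "").strip()
                if not cell:
                    raise ValueError(f"row {i}: missing cell for locus {name}")
                calls[name] = _parse_cell(cell, row=i, column=name)
            haplotypes.append(Haplotype(sample_id=sample_id, calls=calls))
    return haplotypes


def write_haplotype_table(
    path: str | Path,
    haplotypes: Iterable[Haplotype],
    panel: Sequence[LocusSpec],
    delimiter: str | None = None,
) -> None:
    """Write a canonical haplotype table (alleles sorted, ``NEG`` for nulls)."""
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    names = [spec.name for spec in panel]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow([SAMPLE_COLUMN, *names])
        for hap in haplotypes:
            row = [hap.sample_id]
            for name in names:
                row.append(MULTI_ALLELE_SEP.join(a.label for a in hap.calls[name]))
            writer.writerow(row)


def read_pair_manifest(
    path: str | Path, delimiter: str | None = None
) -> list[PairRef]:
    """Read a pair manifest; validates meioses >= 1 and unique family IDs."""
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    refs: list[PairRef] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"family_id", "sample1", "sample2", "meioses"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"pair manifest missing column(s): {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            family_id = row["family_id"].strip()
            if family_id in seen:
                raise ValueError(f"row {i}: duplicate family id {family_id!r}")
            seen.add(family_id)
            try:
                meioses = int(row["meioses"])
            except ValueError as exc:
                raise ValueError(f"row {i}: unparseable meioses {row['meioses']!r}") from exc
            if meioses < 1:
                raise ValueError(f"row {i}: meioses must be >= 1, got {meioses}")
            s1, s2 = row["sample1"].strip(), row["sample2"].strip()
            if s1 == s2:
                raise ValueError(f"row {i}: pair {family_id!r} names the same sample twice")
            refs.append(PairRef(family_id, s1, s2, meioses))
    return refs


def write_pair_manifest(
    path: str | Path, refs: Iterable[PairRef], delimiter: str | None = None
) -> None:
    path = Path(path)
    delim = _delimiter_for(path, delimiter)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["family_id", "sample1", "sample2", "meioses"])
        for ref in refs:
            writer.writerow([ref.family_id, ref.sample1, ref.sample2, ref.meioses])


def join_pairs(
    refs: Iterable[PairRef], haplotypes: Iterable[Haplotype]
) -> list[PedigreePair]:
    """Resolve manifest sample IDs against a haplotype table."""
    by_id = {h.sample_id: h for h in haplotypes}
    pairs = []
    for ref in refs:
        try:
            h1, h2 = by_id[ref.sample1], by_id[ref.sample2]
        except KeyError as exc:
            raise ValueError(
                f"pair {ref.family_id}: sample {exc.args[0]!r} not in haplotype table"
            ) from None
        pairs.append(PedigreePair(ref.family_id, h1, h2, ref.meioses))
    return pairs
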