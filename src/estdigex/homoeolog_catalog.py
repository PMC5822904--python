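"""Catalog of inflorescence development-related gene (IDG) sets.

Hexaploid bread wheat carries three closely related subgenomes (A, B, D);
most genes exist as a homoeologous triad, one copy per subgenome, on one of
seven homoeologous chromosome groups. The screen's output is organized as
nonredundant gene *sets*: an IDG set groups the homoeologous (and
intrachromosomally duplicated) copies that all show inflorescence-predominant
expression.

This module ships the published 59-set catalog as a packaged TSV fixture,
loads it into typed entries, and computes the subgenome/duplication summary
statistics: copy totals, per-chromosome-group distribution, subgenome
presence classes, and duplicated sets.

A subgenome slot without a catalogued copy carries one of three absence
codes: ``a`` — no corresponding gene found; ``b`` — genomic DNA present but
no EST support; ``c`` — the copy exists but is not inflorescence-predominant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AbsenceCode",
    "CatalogEntry",
    "CatalogSummary",
    "SUBGENOMES",
    "load_catalog",
    "presence_class",
    "summarize",
    "format_gene_id",
    "parse_chromosome",
]

SUBGENOMES = ("A", "B", "D")

#: a: gene not found; b: genomic DNA only, no EST support;
#: c: not inflorescence-predominantly expressed.
AbsenceCode = str
_VALID_CODES = {"a", "b", "c"}

_CHROM_RE = re.compile(r"^([1-7])([ABD])$")


def parse_chromosome(token: str) -> tuple[int, str]:
    """Split a chromosome token like '6A' into (homoeologous group, subgenome)."""
    m = _CHROM_RE.match(token.strip())
    if not m:
        raise ValueError(
            f"malformed chromosome token {token!r} (expected group 1-7 + A/B/D)"
        )
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class CatalogEntry:
    """One nonredundant gene set: its copies per chromosome and absence codes."""

    set_id: str
    copies: Mapping[str, int]  # chromosome token -> copy count >= 1
    absent_codes: Mapping[str, AbsenceCode]  # subgenome slot -> code

    def __post_init__(self) -> None:
        occupied = set()
        for chrom, k in self.copies.items():
            _, sub = parse_chromosome(chrom)
            occupied.add(sub)
            if k < 1:
                raise ValueError(f"{self.set_id}: copy count for {chrom} must be >= 1")
        for slot, code in self.absent_codes.items():
            if slot not in SUBGENOMES:
                raise ValueError(f"{self.set_id}: bad subgenome slot {slot!r}")
            if code not in _VALID_CODES:
                raise ValueError(f"{self.set_id}: bad absence code {code!r}")
            if slot in occupied:
                raise ValueError(
                    f"{self.set_id}: subgenome {slot} has both copies and an "
                    f"absence code"
                )

    @property
    def total_copies(self) -> int:
        return sum(self.copies.values())


@dataclass(frozen=True)
class CatalogSummary:
    """Aggregate statistics of the gene catalog."""

    total_genes: int
    total_sets: int
    genes_per_group: Mapping[int, int]
    pct_per_group: Mapping[int, float]  # percent of gene copies, 1 decimal
    presence_counts: Mapping[int, int]  # subgenomes present (1/2/3) -> set count
    dup_sets: tuple[str, ...]
    dup_sets_group6: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "total_sets": self.total_sets,
            "genes_per_group": {str(k): v for k, v in self.genes_per_group.items()},
            "pct_per_group": {str(k): v for k, v in self.pct_per_group.items()},
            "presence_counts": {str(k): v for k, v in self.presence_counts.items()},
            "dup_sets": list(self.dup_sets),
            "dup_sets_group6": list(self.dup_sets_group6),
        }


def _fixture_path() -> Path:
    return Path(str(resources.files("estdigex").joinpath("data/table1_catalog.tsv")))


def load_catalog(path: str | Path | None = None) -> list[CatalogEntry]:
    """Load the catalog TSV (defaults to the packaged published catalog).

    The fixture transcribes the published table as printed, one row per
    subgenome slot. Two documented transcription defects of the source table
    are corrected here, not in the fixture, so the fixture stays diffable
    against the publication:

    * the set list prints "IDG022" twice and never IDG028; the second block
      is loaded as IDG028 (the printed totals are only consistent this way);
    * IDG050 is printed as two duplicate rows (IDG050.1, IDG050.2); they are
      merged into one set with two copies each on 6A and 6D.
    """
    df = pd.read_csv(path if path is not None else _fixture_path(), sep="\t", dtype=str)

    # consecutive rows with one set_id form a block; blocks keep file order
    blocks: list[tuple[str, list[dict]]] = []
    for _, r in df.iterrows():
        sid = str(r["set_id"])
        if not blocks or blocks[-1][0] != sid:
            blocks.append((sid, []))
        blocks[-1][1].append(r)

    # correction 1: second IDG022 block -> IDG028
    seen: set[str] = set()
    fixed: list[tuple[str, list[dict]]] = []
    for sid, rows in blocks:
        if sid in seen:
            if sid == "IDG022":
                sid = "IDG028"
            else:
                raise ValueError(f"duplicate catalog block for {sid!r}")
        seen.add(sid)
        fixed.append((sid, rows))

    # correction 2: merge IDG050.* blocks into IDG050
    merged: dict[str, list[dict]] = {}
    order: list[str] = []
    for sid, rows in fixed:
        base = sid.split(".")[0] if sid.startswith("IDG050.") else sid
        if base not in merged:
            merged[base] = []
            order.append(base)
        merged[base].extend(rows)

    entries: list[CatalogEntry] = []
    for sid in order:
        copies: dict[str, int] = {}
        codes: dict[str, str] = {}
        for r in merged[sid]:
            chrom = str(r["chrom"]).strip()
            k = int(r["copies"])
            code = str(r["code"]).strip()
            slot = str(r["slot"]).strip()
            if chrom != "-":
                parse_chromosome(chrom)
                if k < 1:
                    raise ValueError(f"{sid}: copy count < 1 on {chrom}")
                copies[chrom] = copies.get(chrom, 0) + k
            else:
                codes.setdefault(slot, code)  # first row wins on merge conflicts
        # a slot that gained copies through the merge drops its absence code
        for chrom in copies:
            _, sub = parse_chromosome(chrom)
            codes.pop(sub, None)
        entries.append(CatalogEntry(set_id=sid, copies=copies, absent_codes=codes))
    return entries


def presence_class(entry: CatalogEntry) -> int:
    """Number of distinct subgenomes (A/B/D) holding at least one copy."""
    return len({parse_chromosome(c)[1] for c in entry.copies})


def _round1(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize(catalog: Sequence[CatalogEntry]) -> CatalogSummary:
    """Compute the catalog's distribution statistics.

    Percentages are of gene *copies* (not sets) on each homoeologous group's
    chromosomes, rounded half-up to one decimal. Group membership is a
    property of each chromosome token, so a set spanning groups (e.g. copies
    on 4A and 5D) contributes to both groups.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    total_genes = sum(e.total_copies for e in catalog)
    per_group: dict[int, int] = {g: 0 for g in range(1, 8)}
    for e in catalog:
        for chrom, k in e.copies.items():
            group, _ = parse_chromosome(chrom)
            per_group[group] += k
    pct = {g: _round1(100.0 * per_group[g] / total_genes) for g in per_group}
    presence: dict[int, int] = {1: 0, 2: 0, 3: 0}
    for e in catalog:
        presence[presence_class(e)] += 1
    dup = tuple(e.set_id for e in catalog if any(k > 1 for k in e.copies.values()))
    dup6 = tuple(
        e.set_id
        for e in catalog
        if any(k > 1 and parse_chromosome(c)[0] == 6 for c, k in e.copies.items())
    )
    return CatalogSummary(
        total_genes=total_genes,
        total_sets=len(catalog),
        genes_per_group=per_group,
        pct_per_group=pct,
        presence_counts=presence,
        dup_sets=dup,
        dup_sets_group6=dup6,
    )


def format_gene_id(
    set_index: int, chromosome: str, duplication_index: int | None = None
) -> str:
    """Render a gene name: IDG prefix, 3-digit set number, optional copy
    suffix, chromosome suffix — e.g. ``IDG042.3-6A``, ``IDG001-1A``."""
    if not (1 <= set_index <= 999):
        raise ValueError(f"set_index must lie in 1..999, got {set_index}")
    parse_chromosome(chromosome)
    if duplication_index is not None and duplication_index < 1:
        raise ValueError("duplication_index must be >= 1")
    dup = f".{duplication_index}" if duplication_index is not None else ""
    return f"IDG{set_index:03d}{dup}-{chromosome}"


def catalog_frame(catalog: Iterable[CatalogEntry]) -> pd.DataFrame:
    """Flatten a catalog to one row per chromosome slot (for reports)."""
    rows = []
    for e in catalog:
        for chrom, k in sorted(e.copies.items()):
            rows.append({"set_id": e.set_id, "chrom": chrom, "copies": k, "code": "-"})
        for slot, code in sorted(e.absent_codes.items()):
            rows.append({"set_id": e.set_id, "chrom": "-", "copies": 0, "code": code})
    return pd.DataFrame(rows, columns=["set_id", "chrom", "copies", "code"])
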