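"""Domain types and I/O for EST-pool expression screening.

The sampling unit of the screen is the cDNA library: a collection of cloned
transcripts from one tissue, each sequenced clone contributing one EST.
Libraries are classified into five tissue pools (inflorescence, root, stem,
leaf, seed); the screen compares a gene's matched-EST frequency in the
inflorescence pool against each of the other four pools.

This module holds the typed containers (libraries, gene x library count
matrices, RNA-seq expression profiles), the TSV readers/writers, the
library-inclusion filter, and the pooling step that aggregates per-library
counts into per-tissue pools.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueClass",
    "Tissue",
    "Tier",
    "ESTLibrary",
    "ESTCountMatrix",
    "PoolCounts",
    "Sample",
    "ExpressionProfile",
    "TableFormatError",
    "NegativeCountError",
    "UnknownTissueError",
    "DEFAULT_TISSUE_ALIASES",
    "MIN_LIBRARY_SIZE",
    "CANONICAL_SAMPLES",
    "INFLORESCENCE_STAGES",
    "VEGETATIVE_TISSUES",
    "filter_libraries",
    "pool_counts",
    "read_library_table",
    "write_library_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_expression_table",
    "write_expression_table",
    "write_records",
]


class TissueClass(str, enum.Enum):
    """The five EST-library tissue pools."""

    INFLORESCENCE = "inflorescence"
    ROOT = "root"
    STEM = "stem"
    LEAF = "leaf"
    SEED = "seed"


class Tissue(str, enum.Enum):
    """RNA-seq tissue vocabulary.

    The seed compartment is called GRAIN on the RNA-seq side and SEED on the
    EST-library side; ``EST_POOL_OF_TISSUE`` fixes the mapping.
    """

    INFLORESCENCE = "inflorescence"
    STAMEN = "stamen"
    PISTIL = "pistil"
    ROOT = "root"
    LEAF = "leaf"
    STEM = "stem"
    GRAIN = "grain"


#: RNA-seq tissue -> EST tissue pool (one fixed table for the two vocabularies).
EST_POOL_OF_TISSUE: dict[Tissue, TissueClass] = {
    Tissue.INFLORESCENCE: TissueClass.INFLORESCENCE,
    Tissue.STAMEN: TissueClass.INFLORESCENCE,
    Tissue.PISTIL: TissueClass.INFLORESCENCE,
    Tissue.ROOT: TissueClass.ROOT,
    Tissue.LEAF: TissueClass.LEAF,
    Tissue.STEM: TissueClass.STEM,
    Tissue.GRAIN: TissueClass.SEED,
}

#: Developmental stages of the inflorescence time course (Zadoks scale).
INFLORESCENCE_STAGES: tuple[str, ...] = ("Z32", "Z39", "Z65")

#: Vegetative comparison set used by the classifier and support filter.
VEGETATIVE_TISSUES: tuple[Tissue, ...] = (
    Tissue.ROOT,
    Tissue.LEAF,
    Tissue.STEM,
    Tissue.GRAIN,
)

#: Canonical (tissue, stage) sample set an expression profile must cover.
CANONICAL_SAMPLES: tuple[tuple[Tissue, str], ...] = (
    (Tissue.INFLORESCENCE, "Z32"),
    (Tissue.INFLORESCENCE, "Z39"),
    (Tissue.INFLORESCENCE, "Z65"),
    (Tissue.STAMEN, "meiosis"),
    (Tissue.PISTIL, "heading"),
    (Tissue.ROOT, "seedling"),
    (Tissue.LEAF, "seedling"),
    (Tissue.STEM, "seedling"),
    (Tissue.GRAIN, "dpa10"),
)


class Tier(str, enum.Enum):
    """Homology tier of a count matrix.

    CONTIG_90 is the first-pass screen (ESTs matched to assembled contigs at
    >=90% identity); CDS_99 is the confirmatory re-screen against predicted
    coding sequences at >=99% identity. The matching itself is upstream; tiers
    are labels on precomputed matrices.
    """

    CONTIG_90 = "contig_90"
    CDS_99 = "cds_99"


#: Libraries smaller than this are excluded from profiling.
MIN_LIBRARY_SIZE = 1000

#: Free-text library source descriptions -> tissue pool. User-extensible:
#: pass an augmented mapping to :func:`read_library_table`.
DEFAULT_TISSUE_ALIASES: dict[str, TissueClass] = {
    "inflorescence": TissueClass.INFLORESCENCE,
    "spike": TissueClass.INFLORESCENCE,
    "spikelet": TissueClass.INFLORESCENCE,
    "anther": TissueClass.INFLORESCENCE,
    "pistil": TissueClass.INFLORESCENCE,
    "ovary": TissueClass.INFLORESCENCE,
    "palea": TissueClass.INFLORESCENCE,
    "lemma": TissueClass.INFLORESCENCE,
    "floret": TissueClass.INFLORESCENCE,
    "root": TissueClass.ROOT,
    "stem": TissueClass.STEM,
    "culm": TissueClass.STEM,
    "leaf": TissueClass.LEAF,
    "seedling": TissueClass.LEAF,
    "crown": TissueClass.LEAF,
    "seed": TissueClass.SEED,
    "grain": TissueClass.SEED,
    "kernel": TissueClass.SEED,
    "embryo": TissueClass.SEED,
    "caryopsis": TissueClass.SEED,
}


class TableFormatError(ValueError):
    """A TSV input does not conform to its dialect (bad header, bad token)."""


class NegativeCountError(TableFormatError):
    """A count cell is negative; the message names the offending cell."""


class UnknownTissueError(TableFormatError):
    """A library tissue description has no entry in the alias table."""


@dataclass(frozen=True)
class ESTLibrary:
    """One cDNA library: the sampling unit of the screen."""

    library_id: str
    tissue_class: TissueClass
    est_total: int
    normalized_or_enriched: bool = False

    def __post_init__(self) -> None:
        if self.est_total < 0:
            raise ValueError(
                f"library {self.library_id!r}: est_total must be >= 0, "
                f"got {self.est_total}"
            )
        if not isinstance(self.tissue_class, TissueClass):
            raise ValueError(f"invalid tissue class {self.tissue_class!r}")


@dataclass(frozen=True)
class PoolCounts:
    """Per-gene matched/total EST counts aggregated into tissue pools.

    ``m``/``M`` are matched and total ESTs in the inflorescence pool (their
    ratio estimates the gene's transcript frequency f); ``per_pool`` maps each
    noninflorescence pool to its (n, N) pair. A pool with no retained
    libraries is recorded with N = 0 and is treated downstream as carrying no
    evidence against inflorescence predominance.
    """

    gene_id: str
    m: int
    M: int
    per_pool: Mapping[TissueClass, tuple[int, int]]

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.M):
            raise ValueError(
                f"gene {self.gene_id!r}: need 0 <= m <= M, got m={self.m}, M={self.M}"
            )
        if self.M <= 0:
            raise ValueError(f"gene {self.gene_id!r}: inflorescence pool is empty (M=0)")
        for pool, (n, N) in self.per_pool.items():
            if not (0 <= n <= N):
                raise ValueError(
                    f"gene {self.gene_id!r}, pool {pool.value}: need 0 <= n <= N, "
                    f"got n={n}, N={N}"
                )


class ESTCountMatrix:
    """Gene x library matrix of matched-EST counts at one homology tier."""

    def __init__(
        self,
        tier: Tier,
        genes: Sequence[str],
        libraries: Sequence[str],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(genes), len(libraries)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(genes)} genes x {len(libraries)} libraries"
            )
        if (counts < 0).any():
            g, l = np.argwhere(counts < 0)[0]
            raise NegativeCountError(
                f"negative count at gene {genes[g]!r}, library {libraries[l]!r}: "
                f"{counts[g, l]}"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids are not unique")
        if len(set(libraries)) != len(libraries):
            raise ValueError("library ids are not unique")
        self.tier = tier
        self.genes = list(genes)
        self.libraries = list(libraries)
        self.counts = counts
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._lib_index = {l: j for j, l in enumerate(self.libraries)}

    def gene_counts(self, gene_id: str) -> np.ndarray:
        try:
            return self.counts[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in count matrix") from None

    def validate_against(self, libraries: Sequence[ESTLibrary]) -> None:
        """Check every column's library exists and no count exceeds its size."""
        sizes = {lib.library_id: lib.est_total for lib in libraries}
        for j, lib_id in enumerate(self.libraries):
            if lib_id not in sizes:
                raise TableFormatError(
                    f"library {lib_id!r} in count matrix missing from metadata"
                )
            over = np.argwhere(self.counts[:, j] > sizes[lib_id])
            if over.size:
                g = over[0, 0]
                raise TableFormatError(
                    f"count for gene {self.genes[g]!r} in library {lib_id!r} "
                    f"({self.counts[g, j]}) exceeds library size {sizes[lib_id]}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.libraries)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ESTCountMatrix)
            and self.tier == other.tier
            and self.genes == other.genes
            and self.libraries == other.libraries
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"ESTCountMatrix(tier={self.tier.value}, "
            f"{len(self.genes)} genes x {len(self.libraries)} libraries)"
        )


@dataclass(frozen=True)
class Sample:
    """One RNA-seq sample of one gene: a (tissue, stage) cell of the atlas."""

    tissue: Tissue
    stage: str
    raw_count: int
    mapped_total: int
    gene_length_bp: int

    def __post_init__(self) -> None:
        if self.mapped_total <= 0:
            raise ValueError("mapped_total must be positive")
        if not (0 <= self.raw_count <= self.mapped_total):
            raise ValueError("raw_count must satisfy 0 <= raw_count <= mapped_total")
        if self.gene_length_bp <= 0:
            raise ValueError("gene_length_bp must be positive")

    @property
    def fpkm(self) -> float:
        # fragments * 1e9 / (length * depth); see rnaseq_profiles.fpkm
        return self.raw_count * 1e9 / (self.gene_length_bp * self.mapped_total)


@dataclass
class ExpressionProfile:
    """Gene expression across the tissue/stage atlas (counts plus FPKM)."""

    gene_id: str
    samples: list[Sample] = field(default_factory=list)

    def fpkm_by_tissue_stage(self) -> dict[tuple[Tissue, str], float]:
        return {(s.tissue, s.stage): s.fpkm for s in self.samples}

    def tissue_samples(self, tissue: Tissue) -> list[Sample]:
        return [s for s in self.samples if s.tissue == tissue]

    def max_stage_sample(self, tissue: Tissue) -> Sample | None:
        """The sample with maximal FPKM among a tissue's stages.

        Ties are broken by stage order of appearance so output is
        deterministic.
        """
        best: Sample | None = None
        for s in self.tissue_samples(tissue):
            if best is None or s.fpkm > best.fpkm:
                best = s
        return best

    def tissue_fpkm(self, tissue: Tissue) -> float:
        """Max-over-stages FPKM for a tissue; 0.0 if the tissue is absent."""
        s = self.max_stage_sample(tissue)
        return 0.0 if s is None else s.fpkm


def filter_libraries(libraries: Iterable[ESTLibrary]) -> list[ESTLibrary]:
    """Apply the library-inclusion rule.

    Libraries with fewer than 1000 ESTs, and libraries subjected to
    enrichment or normalization treatment, are excluded (their clone
    frequencies do not reflect transcript abundance). Order is preserved;
    the filter is idempotent.
    """
    return [
        lib
        for lib in libraries
        if lib.est_total >= MIN_LIBRARY_SIZE and not lib.normalized_or_enriched
    ]


def pool_counts(
    matrix: ESTCountMatrix,
    libraries: Sequence[ESTLibrary],
    gene_id: str,
) -> PoolCounts:
    """Aggregate a gene's per-library counts into the five tissue pools.

    m/M sum matched ESTs and library sizes over inflorescence libraries;
    each noninflorescence pool gets its own (n, N). Only libraries present
    in ``matrix`` contribute. Empty pools are recorded as (0, 0).
    """
    by_id = {lib.library_id: lib for lib in libraries}
    for lib_id in matrix.libraries:
        if lib_id not in by_id:
            raise TableFormatError(
                f"library {lib_id!r} in count matrix missing from metadata"
            )
    row = matrix.gene_counts(gene_id)
    matched: dict[TissueClass, int] = {t: 0 for t in TissueClass}
    totals: dict[TissueClass, int] = {t: 0 for t in TissueClass}
    for j, lib_id in enumerate(matrix.libraries):
        lib = by_id[lib_id]
        matched[lib.tissue_class] += int(row[j])
        totals[lib.tissue_class] += lib.est_total
    per_pool = {
        t: (matched[t], totals[t])
        for t in TissueClass
        if t is not TissueClass.INFLORESCENCE
    }
    return PoolCounts(
        gene_id=gene_id,
        m=matched[TissueClass.INFLORESCENCE],
        M=totals[TissueClass.INFLORESCENCE],
        per_pool=per_pool,
    )


# ---------------------------------------------------------------------------
# TSV readers / writers


def read_library_table(
    path: str | Path,
    aliases: Mapping[str, TissueClass] | None = None,
) -> list[ESTLibrary]:
    """Read library metadata TSV: library_id, tissue, est_total, normalized.

    ``tissue`` is a free-text source description resolved through the alias
    table; an unknown alias is an error, never silently dropped.
    """
    aliases = dict(DEFAULT_TISSUE_ALIASES if aliases is None else aliases)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["library_id", "tissue", "est_total", "normalized"]
    if list(df.columns[: len(required)]) != required:
        raise TableFormatError(
            f"library table header must start with {required}, got {list(df.columns)}"
        )
    out: list[ESTLibrary] = []
    for _, r in df.iterrows():
        key = str(r["tissue"]).strip().lower()
        tissue = aliases.get(key)
        if tissue is None:
            # a full class name ("inflorescence") is always acceptable
            try:
                tissue = TissueClass(key)
            except ValueError:
                raise UnknownTissueError(
                    f"library {r['library_id']!r}: unknown tissue alias {key!r}"
                ) from None
        total = int(r["est_total"])
        if total < 0:
            raise NegativeCountError(
                f"library {r['library_id']!r}: est_total is negative ({total})"
            )
        out.append(
            ESTLibrary(
                library_id=str(r["library_id"]),
                tissue_class=tissue,
                est_total=total,
                normalized_or_enriched=bool(int(r["normalized"])),
            )
        )
    return out


def write_library_table(path: str | Path, libraries: Sequence[ESTLibrary]) -> None:
    df = pd.DataFrame(
        {
            "library_id": [l.library_id for l in libraries],
            "tissue": [l.tissue_class.value for l in libraries],
            "est_total": [l.est_total for l in libraries],
            "normalized": [int(l.normalized_or_enriched) for l in libraries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path, tier: Tier) -> ESTCountMatrix:
    """Read a count-matrix TSV: first column gene_id, one column per library."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise TableFormatError(
            f"count matrix must start with a 'gene_id' column, got {df.columns[0]!r}"
        )
    genes = df["gene_id"].astype(str).tolist()
    libs = [str(c) for c in df.columns[1:]]
    counts = df.iloc[:, 1:].to_numpy()
    try:
        counts = counts.astype(np.int64)
    except ValueError as exc:
        raise TableFormatError(f"non-integer count cell in {path}: {exc}") from None
    return ESTCountMatrix(tier=Tier(tier), genes=genes, libraries=libs, counts=counts)


def write_count_matrix(path: str | Path, matrix: ESTCountMatrix) -> None:
    df = matrix.to_frame().reset_index(names="gene_id")
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> list[ExpressionProfile]:
    """Read the long-form expression TSV.

    Columns: gene_id, tissue, stage, raw_count, mapped_total, gene_length_bp.
    Rows for a gene are collected into one profile, preserving row order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "tissue", "stage", "raw_count", "mapped_total", "gene_length_bp"]
    if list(df.columns[: len(required)]) != required:
        raise TableFormatError(
            f"expression table header must start with {required}, got {list(df.columns)}"
        )
    profiles: dict[str, ExpressionProfile] = {}
    for idx, r in df.iterrows():
        gene = str(r["gene_id"])
        try:
            tissue = Tissue(str(r["tissue"]).strip().lower())
        except ValueError:
            raise UnknownTissueError(
                f"row {idx}: unknown RNA-seq tissue {r['tissue']!r}"
            ) from None
        count = int(r["raw_count"])
        if count < 0:
            raise NegativeCountError(
                f"gene {gene!r}, tissue {tissue.value}: raw_count is negative ({count})"
            )
        sample = Sample(
            tissue=tissue,
            stage=str(r["stage"]),
            raw_count=count,
            mapped_total=int(r["mapped_total"]),
            gene_length_bp=int(r["gene_length_bp"]),
        )
        profiles.setdefault(gene, ExpressionProfile(gene_id=gene)).samples.append(sample)
    return list(profiles.values())


def write_expression_table(
    path: str | Path, profiles: Sequence[ExpressionProfile]
) -> None:
    rows = [
        {
            "gene_id": p.gene_id,
            "tissue": s.tissue.value,
            "stage": s.stage,
            "raw_count": s.raw_count,
            "mapped_total": s.mapped_total,
            "gene_length_bp": s.gene_length_bp,
        }
        for p in profiles
        for s in p.samples
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "tissue", "stage", "raw_count", "mapped_total", "gene_length_bp"],
    ).to_csv(path, sep="\t", index=False)


def write_records(
    path: str | Path,
    records: pd.DataFrame,
    summary: Mapping[str, object] | None = None,
) -> None:
    """Write an output TSV with stable column order, plus an optional JSON
    run-summary next to it (same stem, .json suffix)."""
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if summary is not None:
        path.with_suffix(".json").write_text(json.dumps(summary, indent=2, sort_keys=True))
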