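"""Synthetic EST libraries and RNA-seq counts with ground-truth labels.

The screen's sampling model treats a cDNA library as ``est_total`` draws from
the tissue's transcript-frequency distribution; the generator emulates
exactly that: per library a multinomial draw over genes. Inflorescence-
enriched genes are implanted at a stated fold-enrichment of their transcript
frequency, and sole-inflorescence genes at frequency zero outside the
inflorescence, so every screening route has labelled truth.

RNA-seq counts are Poisson draws with mean FPKM_design * length * depth /
1e9 — the inverse of the FPKM formula — so the designed expression surface
is recoverable by the estimator up to sampling noise.

Both generators are deterministic given the design's seed; independent
substreams are split from one seed sequence so adding libraries or genes
does not reshuffle unrelated draws.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .est_model_io import (
    CANONICAL_SAMPLES,
    ESTCountMatrix,
    ESTLibrary,
    ExpressionProfile,
    Sample,
    Tier,
    Tissue,
    TissueClass,
)

__all__ = [
    "TruthLabel",
    "ESTDesign",
    "RNASeqDesign",
    "DEFAULT_LIBRARY_PLAN",
    "default_est_design",
    "null_est_design",
    "generate_est_universe",
    "archetype_rnaseq_design",
    "rnaseq_design_for_est",
    "generate_rnaseq",
]


class TruthLabel(str, enum.Enum):
    # "background" rather than "null": pandas parses the literal string
    # "null" in a TSV as missing data, which would corrupt round-trips
    NULL = "background"
    INFLO_PREDOMINANT = "inflo_predominant"
    SOLE_INFLO = "sole_inflo"
    STAMEN_SPECIFIC = "stamen_specific"
    PISTIL_ENRICHED = "pistil_enriched"
    LOW_DATA = "low_data"


#: Library plan mirroring the study conditions the screen assumes: a few
#: thousand to tens of thousands of clones per library, several libraries per
#: tissue pool, every noninflorescence pool at >= 30,000 ESTs.
DEFAULT_LIBRARY_PLAN: tuple[tuple[TissueClass, int], ...] = (
    (TissueClass.INFLORESCENCE, 20000),
    (TissueClass.INFLORESCENCE, 20000),
    (TissueClass.INFLORESCENCE, 20000),
    (TissueClass.ROOT, 20000),
    (TissueClass.ROOT, 20000),
    (TissueClass.STEM, 15000),
    (TissueClass.STEM, 15000),
    (TissueClass.LEAF, 20000),
    (TissueClass.LEAF, 20000),
    (TissueClass.SEED, 25000),
    (TissueClass.SEED, 25000),
)


@dataclass
class ESTDesign:
    """A designed EST universe: per-tissue transcript frequencies plus truth."""

    n_genes: int
    tissue_profiles: Mapping[TissueClass, np.ndarray]
    truth_labels: list[TruthLabel]
    fold_enrichment: float
    library_plan: tuple[tuple[TissueClass, int], ...]
    seed: int
    tier2_retention: float = 1.0
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            width = len(str(self.n_genes))
            self.gene_ids = [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]
        if len(self.truth_labels) != self.n_genes:
            raise ValueError("truth_labels length must equal n_genes")
        if not (0.0 < self.tier2_retention <= 1.0):
            raise ValueError("tier2_retention must lie in (0, 1]")
        for tissue, p in self.tissue_profiles.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (self.n_genes,) or (p < 0).any():
                raise ValueError(
                    f"{tissue.value}: profile must be a nonnegative vector of "
                    f"length {self.n_genes}"
                )
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"{tissue.value}: profile sums to {p.sum()!r}, not 1"
                )


def _implanted_profiles(
    n_genes: int,
    labels: Sequence[TruthLabel],
    base_frequency: float,
    fold: float,
) -> dict[TissueClass, np.ndarray]:
    """Frequency vectors: implanted genes pinned, null genes share the rest."""
    labels = list(labels)
    null_idx = [i for i, l in enumerate(labels) if l is TruthLabel.NULL]
    if not null_idx:
        raise ValueError("design needs at least one null gene to absorb mass")
    profiles: dict[TissueClass, np.ndarray] = {}
    for tissue in TissueClass:
        p = np.zeros(n_genes)
        for i, label in enumerate(labels):
            if label is TruthLabel.SOLE_INFLO:
                p[i] = base_frequency * fold if tissue is TissueClass.INFLORESCENCE else 0.0
            elif label is TruthLabel.INFLO_PREDOMINANT:
                p[i] = base_frequency * fold if tissue is TissueClass.INFLORESCENCE else base_frequency
        rest = 1.0 - p.sum()
        p[null_idx] = rest / len(null_idx)
        profiles[tissue] = p
    return profiles


def default_est_design(
    seed: int,
    n_genes: int = 200,
    n_sole: int = 10,
    n_predominant: int = 10,
    fold_enrichment: float = 50.0,
    base_frequency: float = 1e-5,
    library_plan: tuple[tuple[TissueClass, int], ...] = DEFAULT_LIBRARY_PLAN,
    tier2_retention: float = 1.0,
) -> ESTDesign:
    """The default implanted design.

    200 genes of which 10 are expressed solely in the inflorescence and 10
    are 50-fold inflorescence-enriched over a 1e-5 baseline frequency
    (implanted frequency 5e-4, so the 60,000-EST inflorescence pool yields
    about 30 matched ESTs per implanted gene); the rest are null genes at a
    common frequency in every tissue.
    """
    labels = (
        [TruthLabel.SOLE_INFLO] * n_sole
        + [TruthLabel.INFLO_PREDOMINANT] * n_predominant
        + [TruthLabel.NULL] * (n_genes - n_sole - n_predominant)
    )
    return ESTDesign(
        n_genes=n_genes,
        tissue_profiles=_implanted_profiles(n_genes, labels, base_frequency, fold_enrichment),
        truth_labels=labels,
        fold_enrichment=fold_enrichment,
        library_plan=tuple(library_plan),
        seed=seed,
        tier2_retention=tier2_retention,
    )


def null_est_design(
    seed: int,
    n_genes: int = 200,
    library_plan: tuple[tuple[TissueClass, int], ...] = DEFAULT_LIBRARY_PLAN,
) -> ESTDesign:
    """A null universe: every gene at the identical frequency in every tissue."""
    uniform = np.full(n_genes, 1.0 / n_genes)
    return ESTDesign(
        n_genes=n_genes,
        tissue_profiles={t: uniform.copy() for t in TissueClass},
        truth_labels=[TruthLabel.NULL] * n_genes,
        fold_enrichment=1.0,
        library_plan=tuple(library_plan),
        seed=seed,
    )


def generate_est_universe(
    design: ESTDesign,
) -> tuple[list[ESTLibrary], dict[Tier, ESTCountMatrix], pd.DataFrame]:
    """Draw the EST universe: libraries, both tier matrices, and truth labels.

    Each library is one multinomial draw of its est_total clones from its
    tissue's frequency vector, so column sums conserve library sizes exactly.
    The CDS tier subsamples each matched EST independently at the design's
    retention rate (1.0 by default, making the tiers identical).
    """
    ss = np.random.SeedSequence(design.seed)
    lib_streams = ss.spawn(len(design.library_plan) + 1)
    libraries: list[ESTLibrary] = []
    columns = []
    tissue_counter: dict[TissueClass, int] = {}
    for k, (tissue, est_total) in enumerate(design.library_plan):
        tissue_counter[tissue] = tissue_counter.get(tissue, 0) + 1
        lib_id = f"lib_{tissue.value}_{tissue_counter[tissue]}"
        libraries.append(
            ESTLibrary(library_id=lib_id, tissue_class=tissue, est_total=est_total)
        )
        rng = np.random.default_rng(lib_streams[k])
        columns.append(rng.multinomial(est_total, design.tissue_profiles[tissue]))
    counts = np.column_stack(columns) if columns else np.zeros((design.n_genes, 0), int)
    lib_ids = [l.library_id for l in libraries]
    tier1 = ESTCountMatrix(Tier.CONTIG_90, design.gene_ids, lib_ids, counts)
    if design.tier2_retention < 1.0:
        rng2 = np.random.default_rng(lib_streams[-1])
        counts2 = rng2.binomial(counts, design.tier2_retention)
    else:
        counts2 = counts.copy()
    tier2 = ESTCountMatrix(Tier.CDS_99, design.gene_ids, lib_ids, counts2)
    truth = pd.DataFrame(
        {"gene_id": design.gene_ids, "truth": [l.value for l in design.truth_labels]}
    )
    return libraries, {Tier.CONTIG_90: tier1, Tier.CDS_99: tier2}, truth


# ---------------------------------------------------------------------------
# RNA-seq side


@dataclass
class RNASeqDesign:
    """Designed FPKM surface: gene x (tissue, stage) -> target FPKM."""

    fpkm_design: Mapping[str, Mapping[tuple[Tissue, str], float]]
    truth: Mapping[str, str]  # gene_id -> designed label (group name or flag)
    seed: int
    gene_length_bp: int = 1500
    depth: int = 10_000_000

    def __post_init__(self) -> None:
        if self.gene_length_bp <= 0 or self.depth <= 0:
            raise ValueError("gene_length_bp and depth must be positive")
        for gene, surface in self.fpkm_design.items():
            for key, v in surface.items():
                if v < 0:
                    raise ValueError(f"{gene}: negative design FPKM at {key}")


#: Designed FPKM per expression-group archetype over the canonical samples.
#: Margins are wide (>= 20x the negligible-FPKM threshold where "expressed",
#: well below it where "negligible") so recovery is deterministic in practice.
_ARCHETYPES: dict[str, dict[str, float]] = {
    # inflorescence-predominant, detectable vegetative background
    "G1-1": {"inflo": 40.0, "stamen": 0.2, "pistil": 0.2, "veg": 1.5},
    # inflorescence-predominant, everything else silent
    "G1-2": {"inflo": 40.0, "stamen": 0.05, "pistil": 0.05, "veg": 0.05},
    # vegetative expression, stamen and pistil higher still
    "G2-1": {"inflo": 50.0, "stamen": 300.0, "pistil": 200.0, "veg": 15.0},
    # vegetative expression, stamen high but pistil at/below vegetative level
    "G2-2": {"inflo": 30.0, "stamen": 300.0, "pistil": 2.0, "veg": 15.0},
    # stamen-specific, inflorescence time course silent
    "G3-1": {"inflo": 0.05, "stamen": 200.0, "pistil": 1.0, "veg": 0.05},
    # stamen-predominant with inflorescence enhancement
    "G3-2": {"inflo": 20.0, "stamen": 200.0, "pistil": 1.0, "veg": 0.05},
}


def _surface_from_archetype(spec: Mapping[str, float]) -> dict[tuple[Tissue, str], float]:
    surface: dict[tuple[Tissue, str], float] = {}
    for tissue, stage in CANONICAL_SAMPLES:
        if tissue is Tissue.INFLORESCENCE:
            value = spec["inflo"]
        elif tissue is Tissue.STAMEN:
            value = spec["stamen"]
        elif tissue is Tissue.PISTIL:
            value = spec["pistil"]
        else:
            value = spec["veg"]
        surface[(tissue, stage)] = value
    return surface


def archetype_rnaseq_design(
    seed: int,
    replicates: int = 5,
    n_low_data: int = 7,
    gene_length_bp: int = 1500,
    depth: int = 10_000_000,
) -> RNASeqDesign:
    """One designed gene set per expression subgroup, plus zero-read genes.

    ``replicates`` genes per subgroup carry that subgroup's archetype FPKM
    surface; ``n_low_data`` genes have design FPKM 0 in every sample and so
    exercise the too-few-reads route.
    """
    fpkm_design: dict[str, dict[tuple[Tissue, str], float]] = {}
    truth: dict[str, str] = {}
    for group, spec in _ARCHETYPES.items():
        for r in range(replicates):
            gene = f"{group.replace('-', '_')}_{r + 1:02d}"
            fpkm_design[gene] = _surface_from_archetype(spec)
            truth[gene] = group
    for r in range(n_low_data):
        gene = f"low_data_{r + 1:02d}"
        fpkm_design[gene] = {key: 0.0 for key in CANONICAL_SAMPLES}
        truth[gene] = "low_data"
    return RNASeqDesign(
        fpkm_design=fpkm_design,
        truth=truth,
        seed=seed,
        gene_length_bp=gene_length_bp,
        depth=depth,
    )


def rnaseq_design_for_est(
    est_design: ESTDesign,
    seed: int,
    gene_length_bp: int = 1500,
    depth: int = 10_000_000,
) -> RNASeqDesign:
    """An RNA-seq surface consistent with an EST design's truth labels.

    Sole-inflorescence genes get the stamen-specific archetype,
    inflorescence-predominant genes the inflorescence-predominant one, and
    null genes a flat surface — so the support filter should retain exactly
    the implanted genes if they reach it.
    """
    flat = {key: 20.0 for key in CANONICAL_SAMPLES}
    by_label = {
        TruthLabel.SOLE_INFLO: _surface_from_archetype(_ARCHETYPES["G3-1"]),
        TruthLabel.INFLO_PREDOMINANT: _surface_from_archetype(_ARCHETYPES["G1-1"]),
        TruthLabel.STAMEN_SPECIFIC: _surface_from_archetype(_ARCHETYPES["G3-1"]),
        TruthLabel.PISTIL_ENRICHED: _surface_from_archetype(_ARCHETYPES["G2-1"]),
    }
    fpkm_design = {}
    truth = {}
    for gene, label in zip(est_design.gene_ids, est_design.truth_labels):
        fpkm_design[gene] = dict(by_label.get(label, flat))
        truth[gene] = label.value
    return RNASeqDesign(
        fpkm_design=fpkm_design,
        truth=truth,
        seed=seed,
        gene_length_bp=gene_length_bp,
        depth=depth,
    )


def generate_rnaseq(design: RNASeqDesign) -> list[ExpressionProfile]:
    """Draw Poisson read counts from the designed FPKM surface.

    count ~ Poisson(FPKM_design * length_bp * depth / 1e9) per gene per
    sample; a design FPKM of 0 always yields count 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed))
    profiles: list[ExpressionProfile] = []
    for gene, surface in design.fpkm_design.items():
        samples = []
        for (tissue, stage), target in surface.items():
            lam = target * design.gene_length_bp * design.depth / 1e9
            count = int(rng.poisson(lam)) if lam > 0 else 0
            samples.append(
                Sample(
                    tissue=tissue,
                    stage=stage,
                    raw_count=count,
                    mapped_total=design.depth,
                    gene_length_bp=design.gene_length_bp,
                )
            )
        profiles.append(ExpressionProfile(gene_id=gene, samples=samples))
    return profiles
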