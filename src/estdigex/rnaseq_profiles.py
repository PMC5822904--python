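"""RNA-seq-side expression statistics.

FPKM normalization, the relative-expression-specificity (RES) index, the
Pearson chi-square test for a count difference between two samples, the
heat-map relative-abundance transform, and the 2^-ddCt relative-quantity
formula used for qPCR cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .est_model_io import ExpressionProfile, Tissue

__all__ = [
    "RESRecord",
    "ChiSquareResult",
    "TISSUE_ORDER",
    "fpkm",
    "res",
    "chi_square_diff",
    "relative_abundance",
    "ddct_fold_change",
]

#: Canonical tissue order; used to break argmax ties deterministically.
TISSUE_ORDER: tuple[Tissue, ...] = (
    Tissue.INFLORESCENCE,
    Tissue.STAMEN,
    Tissue.PISTIL,
    Tissue.ROOT,
    Tissue.LEAF,
    Tissue.STEM,
    Tissue.GRAIN,
)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RESRecord:
    """Relative expression specificity of a gene in a focal tissue A.

    res = (expr_A - expr_B) / expr_A where B is the most highly expressed
    tissue among the comparison set. res = 1 means exclusive expression in A;
    negative values mean some other tissue exceeds A. Undefined (and so
    flagged) when expr_A = 0.
    """

    gene_id: str
    tissue_a: Tissue
    tissue_b: Tissue | None
    res: float
    defined: bool


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square comparison of two count proportions (df = 1)."""

    statistic: float
    df: int
    p_value: float
    significant: bool


def fpkm(raw_count: int, gene_length_bp: int, mapped_total: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads.

    raw_count * 1e9 / (gene_length_bp * mapped_total): normalizes a read
    count by transcript length (kb) and sequencing depth (millions).
    """
    if gene_length_bp <= 0:
        raise ValueError(f"gene_length_bp must be positive, got {gene_length_bp}")
    if mapped_total <= 0:
        raise ValueError(f"mapped_total must be positive, got {mapped_total}")
    if raw_count < 0:
        raise ValueError(f"raw_count must be >= 0, got {raw_count}")
    return raw_count * 1e9 / (gene_length_bp * mapped_total)


def res(
    profile: ExpressionProfile,
    tissue_a: Tissue,
    comparison_set: set[Tissue] | frozenset[Tissue],
) -> RESRecord:
    """Relative expression specificity of ``tissue_a`` against a comparison set.

    Expression values are max-over-stages FPKM per tissue. B is the argmax
    over the comparison set, ties broken by the canonical tissue order.
    """
    if tissue_a in comparison_set:
        raise ValueError(f"focal tissue {tissue_a.value} is in the comparison set")
    if not comparison_set:
        raise ValueError("comparison set is empty")
    expr_a = profile.tissue_fpkm(tissue_a)
    ordered = [t for t in TISSUE_ORDER if t in comparison_set]
    # any comparison tissue outside the canonical order goes last, name order
    ordered += sorted(
        (t for t in comparison_set if t not in TISSUE_ORDER), key=lambda t: t.value
    )
    tissue_b = max(ordered, key=lambda t: (profile.tissue_fpkm(t), -ordered.index(t)))
    expr_b = profile.tissue_fpkm(tissue_b)
    if expr_a == 0.0:
        return RESRecord(profile.gene_id, tissue_a, tissue_b, float("nan"), False)
    return RESRecord(
        profile.gene_id, tissue_a, tissue_b, (expr_a - expr_b) / expr_a, True
    )


def chi_square_diff(
    count_a: int,
    depth_a: int,
    count_b: int,
    depth_b: int,
    *,
    alpha: float = DEFAULT_ALPHA,
    yates: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square test of equal proportions between two samples.

    The 2x2 table is [[count, depth - count] per sample]; df = 1; no
    continuity correction by default (``yates`` enables it). Significance is
    strict: p < alpha.
    """
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("depths must be positive")
    if not (0 <= count_a <= depth_a and 0 <= count_b <= depth_b):
        raise ValueError("counts must satisfy 0 <= count <= depth")
    table = np.array(
        [[count_a, depth_a - count_a], [count_b, depth_b - count_b]], dtype=float
    )
    # a zero margin (both counts 0, or both equal to depth) carries no
    # evidence of a difference; scipy rejects the degenerate table
    if (table.sum(axis=0) == 0).any():
        return ChiSquareResult(0.0, 1, 1.0, False)
    stat, p, dof, _ = chi2_contingency(table, correction=yates)
    return ChiSquareResult(float(stat), int(dof), float(p), bool(p < alpha))


def relative_abundance(
    fpkm_by_tissue_stage: dict[tuple[Tissue, str], float],
    gene_set_mean: float,
    *,
    log_base: float = 2.0,
    epsilon: float = 0.01,
) -> dict[Tissue, float]:
    """Heat-map relative abundance of one gene per tissue.

    Per tissue the max-over-stages FPKM is divided by the mean FPKM of the
    whole gene set, then log-transformed with a pseudocount:
    log2(quotient + epsilon). A gene absent from a tissue maps to
    log2(epsilon), the floor of the scale.
    """
    if gene_set_mean <= 0:
        raise ValueError(f"gene_set_mean must be positive, got {gene_set_mean}")
    per_tissue: dict[Tissue, float] = {}
    for (tissue, _stage), value in fpkm_by_tissue_stage.items():
        per_tissue[tissue] = max(per_tissue.get(tissue, 0.0), value)
    log = np.log2 if log_base == 2.0 else (lambda x: np.log(x) / np.log(log_base))
    return {
        tissue: float(log(value / gene_set_mean + epsilon))
        for tissue, value in per_tissue.items()
    }


def ddct_fold_change(delta_delta_ct: float) -> float:
    """Relative expression from qPCR cycle thresholds: 2^(-ddCt).

    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator;
    each PCR cycle doubles the product, so one cycle earlier means twofold more
    transcript.
    """
    return float(2.0 ** (-delta_delta_ct))
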