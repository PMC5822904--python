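"""Expression-group taxonomy over RNA-seq profiles.

Genes that survive the EST screen fall into three expression groups, each
with two subgroups, by where their RNA-seq expression concentrates:

* G1 — predominance of the inflorescence as a whole (the spike time course),
  G1-2 if expression everywhere else is negligible, else G1-1.
* G2 — expression in one or more vegetative tissues but an even higher level
  in stamen and/or pistil; G2-1 if the pistil is significantly above every
  vegetative tissue, else G2-2.
* G3 — stamen-predominant with negligible vegetative expression; G3-1 if the
  inflorescence time course itself is negligible, else G3-2 (inflorescence
  also significantly above the vegetative tissues).

Genes negligible in every tissue are routed to LOW_DATA (too few reads to
profile); genes matching no clause are UNCLASSIFIED. Precedence G3 > G2 > G1
resolves overlaps; every clause evaluated is preserved in an evidence map so
assignments can be audited and re-derived.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .est_model_io import (
    CANONICAL_SAMPLES,
    VEGETATIVE_TISSUES,
    ExpressionProfile,
    Sample,
    Tissue,
)
from .rnaseq_profiles import DEFAULT_ALPHA, chi_square_diff, res

__all__ = [
    "Group",
    "GroupAssignment",
    "IncompleteProfileError",
    "DEFAULT_NEGLIGIBLE_FPKM",
    "classify_gene",
    "classify_all",
]

#: FPKM below which a tissue's expression is treated as negligible.
DEFAULT_NEGLIGIBLE_FPKM = 0.5


class Group(str, enum.Enum):
    G1_1 = "G1-1"
    G1_2 = "G1-2"
    G2_1 = "G2-1"
    G2_2 = "G2-2"
    G3_1 = "G3-1"
    G3_2 = "G3-2"
    UNCLASSIFIED = "unclassified"
    LOW_DATA = "low_data"


class IncompleteProfileError(ValueError):
    """The profile does not cover the canonical tissue/stage sample set."""


@dataclass(frozen=True)
class GroupAssignment:
    gene_id: str
    group: Group
    evidence: Mapping[str, bool]


def _require_canonical(profile: ExpressionProfile) -> None:
    have = {(s.tissue, s.stage) for s in profile.samples}
    missing = [f"{t.value}/{st}" for t, st in CANONICAL_SAMPLES if (t, st) not in have]
    if missing:
        raise IncompleteProfileError(
            f"gene {profile.gene_id!r}: profile missing samples {missing}"
        )


def _sig_higher(a: Sample, b: Sample, alpha: float) -> bool:
    """Is sample a's expression significantly higher than sample b's?

    Chi-square on raw counts vs depths, plus the direction requirement that
    a's FPKM exceed b's (the test itself is two-sided).
    """
    result = chi_square_diff(
        a.raw_count, a.mapped_total, b.raw_count, b.mapped_total, alpha=alpha
    )
    return result.significant and a.fpkm > b.fpkm


def classify_gene(
    profile: ExpressionProfile,
    negligible_fpkm: float = DEFAULT_NEGLIGIBLE_FPKM,
    alpha: float = DEFAULT_ALPHA,
) -> GroupAssignment:
    """Assign one gene to its expression group.

    Evaluation order G3 -> G2 -> G1 -> UNCLASSIFIED, after the LOW_DATA
    check. Within a tissue the stage with maximal FPKM represents the tissue
    both for the FPKM threshold and for the pairwise significance calls
    (max-over-stages rule). Significance reuses the Pearson chi-square on raw
    counts at ``alpha``.
    """
    _require_canonical(profile)

    rep: dict[Tissue, Sample] = {}
    for tissue in Tissue:
        s = profile.max_stage_sample(tissue)
        if s is not None:
            rep[tissue] = s

    f = {t: s.fpkm for t, s in rep.items()}
    veg = list(VEGETATIVE_TISSUES)

    def sig_above_all_veg(t: Tissue) -> bool:
        return all(_sig_higher(rep[t], rep[v], alpha) for v in veg)

    ev: dict[str, bool] = {}
    ev["all_tissues_negligible"] = all(v < negligible_fpkm for v in f.values())
    ev["veg_all_negligible"] = all(f[v] < negligible_fpkm for v in veg)
    ev["any_veg_expressed"] = not ev["veg_all_negligible"]
    ev["stamen_expressed"] = f[Tissue.STAMEN] >= negligible_fpkm
    ev["inflo_negligible"] = f[Tissue.INFLORESCENCE] < negligible_fpkm
    ev["stamen_sig_above_veg"] = sig_above_all_veg(Tissue.STAMEN)
    ev["pistil_sig_above_veg"] = sig_above_all_veg(Tissue.PISTIL)
    ev["inflo_sig_above_veg"] = sig_above_all_veg(Tissue.INFLORESCENCE)
    ev["stamen_pistil_veg_negligible"] = (
        f[Tissue.STAMEN] < negligible_fpkm
        and f[Tissue.PISTIL] < negligible_fpkm
        and ev["veg_all_negligible"]
    )

    if ev["all_tissues_negligible"]:
        return GroupAssignment(profile.gene_id, Group.LOW_DATA, ev)

    # G3: stamen-predominant, vegetative silence
    if ev["veg_all_negligible"] and ev["stamen_expressed"] and ev["stamen_sig_above_veg"]:
        if ev["inflo_negligible"]:
            return GroupAssignment(profile.gene_id, Group.G3_1, ev)
        if ev["inflo_sig_above_veg"]:
            return GroupAssignment(profile.gene_id, Group.G3_2, ev)

    # G2: vegetative expression present but stamen/pistil higher still
    if ev["any_veg_expressed"] and (
        ev["stamen_sig_above_veg"] or ev["pistil_sig_above_veg"]
    ):
        group = Group.G2_1 if ev["pistil_sig_above_veg"] else Group.G2_2
        return GroupAssignment(profile.gene_id, group, ev)

    # G1: inflorescence-as-a-whole predominance
    if ev["inflo_sig_above_veg"]:
        group = Group.G1_2 if ev["stamen_pistil_veg_negligible"] else Group.G1_1
        return GroupAssignment(profile.gene_id, group, ev)

    return GroupAssignment(profile.gene_id, Group.UNCLASSIFIED, ev)


def classify_all(
    profiles: Sequence[ExpressionProfile],
    negligible_fpkm: float = DEFAULT_NEGLIGIBLE_FPKM,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[GroupAssignment], dict[str, int]]:
    """Classify every profile; returns assignments plus per-group counts.

    Pure function of the profiles and parameters: permutation of the input
    permutes the output identically. LOW_DATA genes appear in the summary
    under their own key, mirroring their exclusion from the expression
    heat map.
    """
    assignments = [classify_gene(p, negligible_fpkm, alpha) for p in profiles]
    summary = Counter(a.group.value for a in assignments)
    return assignments, dict(summary)


def assignment_frame(assignments: Sequence[GroupAssignment], profiles: Sequence[ExpressionProfile]):
    """Output-table rows: group plus the three focal RES values per gene."""
    import json

    import pandas as pd

    by_id = {p.gene_id: p for p in profiles}
    rows = []
    for a in assignments:
        p = by_id[a.gene_id]
        others = set(Tissue)
        row = {"gene_id": a.gene_id, "group": a.group.value}
        for focal, col in [
            (Tissue.STAMEN, "res_stamen"),
            (Tissue.PISTIL, "res_pistil"),
            (Tissue.INFLORESCENCE, "res_inflorescence"),
        ]:
            r = res(p, focal, others - {focal})
            row[col] = r.res
        row["evidence_json"] = json.dumps(dict(a.evidence), sort_keys=True)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "group",
            "res_stamen",
            "res_pistil",
            "res_inflorescence",
            "evidence_json",
        ],
    )
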