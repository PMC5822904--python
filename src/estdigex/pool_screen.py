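"""Digital differential-expression screen over pooled EST counts.

A gene's transcript frequency f in the inflorescence pool is estimated as
m/M (matched ESTs over pool size). For each noninflorescence pool the
probability of drawing its observed n matched ESTs out of N sampled clones,
were the gene expressed at frequency f there too, is the binomial point
probability

    P(n; N, f) = C(N, n) f^n (1 - f)^(N - n)

A small P for an n far below the expectation f*N is evidence that the gene
is expressed at a lower frequency in that tissue, i.e. that it is
inflorescence-predominant. Genes pass the screen either because every other
pool has zero matched ESTs (the "sole-inflorescence" route) or because every
nonempty pool is individually significant at the tier's threshold.

The statistic is the point probability mass, not a tail sum; an optional
cumulative variant (sum over k <= n) is available for sensitivity analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy.special import gammaln

from .est_model_io import (
    ESTCountMatrix,
    ESTLibrary,
    PoolCounts,
    Tier,
    TissueClass,
    pool_counts,
)

__all__ = [
    "Route",
    "ScreenRecord",
    "DEFAULT_THRESHOLDS",
    "pool_est_frequency",
    "sampling_probability",
    "log_sampling_probability",
    "screen_gene",
    "run_screen",
    "records_to_frame",
]

#: Default significance thresholds per homology tier: the first-pass contig
#: screen uses 1e-4; the confirmatory CDS re-screen uses 1e-2.
DEFAULT_THRESHOLDS: dict[Tier, float] = {Tier.CONTIG_90: 1e-4, Tier.CDS_99: 1e-2}


class Route(str, enum.Enum):
    SOLE = "sole"  # matched ESTs solely from inflorescence libraries
    SIGNIFICANT = "significant"  # every nonempty pool individually significant
    FAIL = "fail"


@dataclass(frozen=True)
class ScreenRecord:
    """Per-gene screening outcome at one homology tier."""

    gene_id: str
    tier: Tier
    f: float
    per_pool_probability: Mapping[TissueClass, float]
    sole_inflorescence: bool
    passes: bool
    route: Route


def pool_est_frequency(m: int, M: int) -> float:
    """EST frequency of a gene in a pool: matched ESTs over pool size."""
    if M <= 0:
        raise ZeroDivisionError("pool has no ESTs (M = 0): frequency undefined")
    if not (0 <= m <= M):
        raise ValueError(f"need 0 <= m <= M, got m={m}, M={M}")
    return m / M


def log_sampling_probability(n: int, N: int, f: float) -> float:
    """Natural log of the binomial point probability C(N,n) f^n (1-f)^(N-n).

    The log-gamma form of the coefficient keeps the evaluation exact to
    floating precision for pools of tens of thousands of ESTs, where the
    probability itself can underflow. Edge conventions: f = 0 gives log 1 = 0
    iff n = 0 (the 0^0 = 1 convention) and -inf otherwise; symmetrically for
    f = 1.
    """
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"frequency f must lie in [0, 1], got {f}")
    if f == 0.0:
        return 0.0 if n == 0 else -math.inf
    if f == 1.0:
        return 0.0 if n == N else -math.inf
    log_coeff = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    return float(log_coeff + n * math.log(f) + (N - n) * math.log1p(-f))


def sampling_probability(
    n: int, N: int, f: float, *, tail_sum: bool = False
) -> float:
    """Binomial point probability C(N,n) f^n (1-f)^(N-n).

    Exponentiates :func:`log_sampling_probability`; underflows to 0.0 only
    when the probability is below the smallest positive float.

    With ``tail_sum`` the lower-tail cumulative sum over k = 0..n is returned
    instead (sensitivity-analysis variant, never the default).
    """
    if tail_sum:
        return math.fsum(sampling_probability(k, N, f) for k in range(n + 1))
    return float(math.exp(log_sampling_probability(n, N, f)))


def screen_gene(
    pc: PoolCounts,
    threshold: float,
    *,
    tier: Tier = Tier.CONTIG_90,
    tail_sum: bool = False,
    merged_pool: bool = False,
    direction_guard: bool = True,
) -> ScreenRecord:
    """Decide whether one gene is inflorescence-predominant.

    Routes:

    * SOLE — m > 0 and every other pool has n = 0 (threshold-independent).
    * SIGNIFICANT — m > 0 and every pool with N > 0 either has n = 0 or is
      individually significant: P <= threshold, and (by default) the pool's
      observed frequency n/N lies below f, so that a significantly *enriched*
      pool can never count as evidence of predominance.
    * FAIL — otherwise. Empty pools (N = 0) never block a pass.

    ``merged_pool`` collapses the four noninflorescence pools into one before
    testing (comparison against the union rather than each tissue).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    f = pool_est_frequency(pc.m, pc.M)

    pools: Mapping[TissueClass, tuple[int, int]]
    if merged_pool:
        n_tot = sum(n for n, _ in pc.per_pool.values())
        N_tot = sum(N for _, N in pc.per_pool.values())
        pools = {t: (n_tot, N_tot) for t in pc.per_pool}
    else:
        pools = pc.per_pool

    probs: dict[TissueClass, float] = {}
    for tcls, (n, N) in pools.items():
        probs[tcls] = sampling_probability(n, N, f, tail_sum=tail_sum) if N > 0 else 1.0

    sole = pc.m > 0 and all(n == 0 for n, _ in pc.per_pool.values())
    if sole:
        route = Route.SOLE
    elif pc.m > 0:

        def pool_ok(tcls: TissueClass) -> bool:
            n, N = pools[tcls]
            if N == 0 or n == 0:
                return True
            if probs[tcls] > threshold:
                return False
            return (n / N) < f if direction_guard else True

        route = Route.SIGNIFICANT if all(pool_ok(t) for t in pools) else Route.FAIL
    else:
        route = Route.FAIL

    return ScreenRecord(
        gene_id=pc.gene_id,
        tier=tier,
        f=f,
        per_pool_probability=probs,
        sole_inflorescence=sole,
        passes=route is not Route.FAIL,
        route=route,
    )


def run_screen(
    matrix: ESTCountMatrix,
    libraries: Sequence[ESTLibrary],
    threshold: float | None = None,
    *,
    tail_sum: bool = False,
    merged_pool: bool = False,
    direction_guard: bool = True,
) -> list[ScreenRecord]:
    """Screen every gene of a count matrix; one record per gene, matrix order.

    The threshold defaults to the matrix tier's convention (1e-4 for the
    contig tier, 1e-2 for the CDS tier). Deterministic: no randomness, stable
    ordering. No multiple-testing correction is applied; the record count is
    reported so users can adjust post hoc.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[matrix.tier]
    matrix.validate_against(libraries)
    records = []
    for gene in matrix.genes:
        pc = pool_counts(matrix, libraries, gene)
        records.append(
            screen_gene(
                pc,
                threshold,
                tier=matrix.tier,
                tail_sum=tail_sum,
                merged_pool=merged_pool,
                direction_guard=direction_guard,
            )
        )
    return records


def records_to_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    """Flatten screen records to the output-table schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "tier": r.tier.value,
                "f": r.f,
                "P_root": r.per_pool_probability.get(TissueClass.ROOT, float("nan")),
                "P_stem": r.per_pool_probability.get(TissueClass.STEM, float("nan")),
                "P_leaf": r.per_pool_probability.get(TissueClass.LEAF, float("nan")),
                "P_seed": r.per_pool_probability.get(TissueClass.SEED, float("nan")),
                "sole": r.sole_inflorescence,
                "route": r.route.value,
                "passes": r.passes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "tier",
            "f",
            "P_root",
            "P_stem",
            "P_leaf",
            "P_seed",
            "sole",
            "route",
            "passes",
        ],
    )
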