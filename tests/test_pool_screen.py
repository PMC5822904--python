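"""Sampling-probability statistic and screening decision rules."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estdigex.est_model_io import PoolCounts, Tier, TissueClass
from estdigex.pool_screen import (
    Route,
    log_sampling_probability,
    pool_est_frequency,
    run_screen,
    sampling_probability,
    screen_gene,
)
from estdigex.synthetic_data import default_est_design, generate_est_universe

from conftest import exact_log_pmf

NONINFL = [TissueClass.ROOT, TissueClass.STEM, TissueClass.LEAF, TissueClass.SEED]


def make_pool_counts(m, M, **pools):
    """PoolCounts with named overrides, e.g. leaf=(5, 50000); others (0, 30000)."""
    per_pool = {t: pools.get(t.value, (0, 30000)) for t in NONINFL}
    return PoolCounts(gene_id="g", m=m, M=M, per_pool=per_pool)


class TestPoolESTFrequency:
    @pytest.mark.parametrize(
        "m, M, expected", [(10, 100000, 1e-4), (0, 50000, 0.0), (50000, 50000, 1.0)]
    )
    def test_exact_division(self, m, M, expected):
        assert pool_est_frequency(m, M) == expected

    def test_zero_pool_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            pool_est_frequency(0, 0)


class TestSamplingProbability:
    @pytest.mark.parametrize(
        "n, N, f, expected",
        [
            (0, 100, 0.0, 1.0),  # 0^0 convention
            (5, 100, 0.0, 0.0),
            (10, 10, 1.0, 1.0),  # certain event
            (3, 10, 1.0, 0.0),
            # frozen from exact evaluation: 0.999**1000
            (0, 1000, 0.001, 0.3676954247709639),
            # frozen from exact rational arithmetic: 45 * 0.1^2 * 0.9^8
            (2, 10, 0.1, 0.19371024450000005),
        ],
    )
    def test_point_values(self, n, N, f, expected):
        assert sampling_probability(n, N, f) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n, N, f", [(-1, 10, 0.5), (11, 10, 0.5), (1, 10, 1.5)])
    def test_domain_errors(self, n, N, f):
        with pytest.raises(ValueError):
            sampling_probability(n, N, f)

    @pytest.mark.parametrize("N", [1, 7, 50, 200])
    @pytest.mark.parametrize("f", [1e-5, 0.01, 0.3, 0.5])
    def test_normalization(self, N, f):
        total = math.fsum(sampling_probability(n, N, f) for n in range(N + 1))
        assert abs(total - 1.0) < 1e-10

    def test_agrees_with_exact_rational_oracle_on_grid(self):
        fs = [
            Fraction(1, 100000),
            Fraction(1, 1000),
            Fraction(1, 100),
            Fraction(1, 10),
            Fraction(1, 2),
        ]
        worst = 0.0
        for N in [10, 100, 1000, 10000]:
            for f in fs:
                step = max(1, N // 8)
                for n in range(0, N + 1, step):
                    got = log_sampling_probability(n, N, float(f))
                    worst = max(worst, abs(got - exact_log_pmf(n, N, f)))
        assert worst <= 1e-9

    def test_tail_sum_is_cumulative(self):
        point = [sampling_probability(k, 20, 0.2) for k in range(6)]
        assert sampling_probability(5, 20, 0.2, tail_sum=True) == pytest.approx(
            math.fsum(point), abs=1e-12
        )


class TestScreenGene:
    def test_sole_route_when_all_other_pools_empty_of_matches(self):
        rec = screen_gene(make_pool_counts(15, 30000), threshold=1e-4)
        assert rec.route is Route.SOLE and rec.passes and rec.sole_inflorescence

    def test_no_inflorescence_evidence_fails(self):
        rec = screen_gene(make_pool_counts(0, 30000), threshold=1e-4)
        assert rec.route is Route.FAIL and not rec.passes

    def test_marginal_leaf_pool_blocks_tier1_pass(self):
        # f = 2e-4; leaf observes 5 of 50000: P ~ 0.0378 > 1e-4
        rec = screen_gene(
            make_pool_counts(20, 100000, leaf=(5, 50000)), threshold=1e-4
        )
        assert rec.per_pool_probability[TissueClass.LEAF] == pytest.approx(
            0.0378, abs=2e-4
        )
        assert rec.route is Route.FAIL

    def test_empty_pool_never_blocks(self):
        rec = screen_gene(
            make_pool_counts(15, 30000, stem=(0, 0)), threshold=1e-4
        )
        assert rec.passes

    def test_significant_route_with_depleted_pool(self):
        # f = 5e-4, root observes 1 of 40000 where 20 were expected
        rec = screen_gene(
            make_pool_counts(30, 60000, root=(1, 40000)), threshold=1e-4
        )
        assert rec.route is Route.SIGNIFICANT and rec.passes

    def test_direction_guard_rejects_enriched_pool(self):
        # root hugely ENRICHED (200 of 30000 vs f = 1e-4): point pmf is tiny,
        # so only the direction guard separates enrichment from depletion
        pc = make_pool_counts(3, 30000, root=(200, 30000))
        assert not screen_gene(pc, threshold=1e-2).passes
        assert screen_gene(pc, threshold=1e-2, direction_guard=False).passes

    def test_sole_route_is_threshold_independent(self):
        pc = make_pool_counts(15, 30000)
        for thr in (1e-8, 1e-4, 0.5):
            assert screen_gene(pc, thr).route is Route.SOLE

    @given(
        m=st.integers(1, 50),
        n=st.integers(0, 40),
        thr_pair=st.tuples(
            st.floats(1e-8, 0.5), st.floats(1e-8, 0.5)
        ).map(sorted),
    )
    @settings(max_examples=60, deadline=None)
    def test_raising_threshold_never_unpasses(self, m, n, thr_pair):
        lo, hi = thr_pair
        pc = make_pool_counts(m, 30000, root=(n, 30000))
        if screen_gene(pc, lo).passes:
            assert screen_gene(pc, hi).passes


class TestRunScreen:
    def test_tier_threshold_separates_tiers(self):
        # construct counts whose P lies in (1e-4, 1e-2]: f=5e-4, root n=7 of
        # 40000 (expected 20) gives P ~ 2.6e-3
        pc = make_pool_counts(30, 60000, root=(7, 40000))
        p = screen_gene(pc, 0.5).per_pool_probability[TissueClass.ROOT]
        assert 1e-4 < p <= 1e-2
        assert not screen_gene(pc, 1e-4).passes
        assert screen_gene(pc, 1e-2).passes

    def test_screen_is_deterministic_and_ordered(self):
        design = default_est_design(seed=11)
        libraries, matrices, _ = generate_est_universe(design)
        first = run_screen(matrices[Tier.CONTIG_90], libraries)
        second = run_screen(matrices[Tier.CONTIG_90], libraries)
        assert first == second
        assert [r.gene_id for r in first] == matrices[Tier.CONTIG_90].genes
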