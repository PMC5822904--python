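"""FPKM, RES, chi-square, heat-map transform, and qPCR fold-change."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estdigex.est_model_io import ExpressionProfile, Sample, Tissue
from estdigex.rnaseq_profiles import (
    chi_square_diff,
    ddct_fold_change,
    fpkm,
    relative_abundance,
    res,
)


def profile_from_fpkm(values: dict[Tissue, float], depth=10_000_000, length=1000):
    """Build a profile whose per-tissue FPKM equals the requested values."""
    samples = []
    for tissue, v in values.items():
        count = round(v * length * depth / 1e9)
        samples.append(Sample(tissue, "s1", count, depth, length))
    return ExpressionProfile("g", samples)


class TestFPKM:
    @pytest.mark.parametrize(
        "count, length, depth, expected",
        [(100, 1000, 10**6, 100.0), (0, 2000, 10**7, 0.0), (10, 2000, 2 * 10**7, 0.25)],
    )
    def test_closed_form(self, count, length, depth, expected):
        assert fpkm(count, length, depth) == pytest.approx(expected, abs=1e-8)

    def test_linearity_and_scaling(self):
        base = fpkm(50, 1500, 10**7)
        assert fpkm(100, 1500, 10**7) == pytest.approx(2 * base)
        assert fpkm(50, 3000, 10**7) == pytest.approx(base / 2)
        assert fpkm(50, 1500, 2 * 10**7) == pytest.approx(base / 2)

    @pytest.mark.parametrize("length, depth", [(0, 10**6), (1000, 0), (-5, 10**6)])
    def test_domain_errors(self, length, depth):
        with pytest.raises(ValueError):
            fpkm(10, length, depth)


class TestRES:
    def test_most_expressed_other_tissue_is_b(self):
        p = profile_from_fpkm(
            {Tissue.STAMEN: 10.0, Tissue.ROOT: 2.0, Tissue.LEAF: 5.0, Tissue.STEM: 1.0}
        )
        r = res(p, Tissue.STAMEN, {Tissue.ROOT, Tissue.LEAF, Tissue.STEM})
        assert r.tissue_b is Tissue.LEAF
        assert r.res == pytest.approx(0.5)

    def test_exclusive_expression_gives_one(self):
        p = profile_from_fpkm(
            {Tissue.STAMEN: 10.0, Tissue.ROOT: 0.0, Tissue.LEAF: 0.0}
        )
        r = res(p, Tissue.STAMEN, {Tissue.ROOT, Tissue.LEAF})
        assert r.res == 1.0

    def test_negative_specificity(self):
        p = profile_from_fpkm({Tissue.STAMEN: 5.0, Tissue.ROOT: 10.0})
        r = res(p, Tissue.STAMEN, {Tissue.ROOT})
        assert r.res == pytest.approx(-1.0)

    def test_silent_focal_tissue_is_undefined(self):
        p = profile_from_fpkm({Tissue.STAMEN: 0.0, Tissue.ROOT: 10.0})
        r = res(p, Tissue.STAMEN, {Tissue.ROOT})
        assert not r.defined

    @given(scale=st.integers(1, 1000))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = {Tissue.STAMEN: 8.0, Tissue.ROOT: 2.0, Tissue.LEAF: 3.0}
        scaled = {t: v * scale for t, v in base.items()}
        r1 = res(profile_from_fpkm(base), Tissue.STAMEN, {Tissue.ROOT, Tissue.LEAF})
        r2 = res(profile_from_fpkm(scaled), Tissue.STAMEN, {Tissue.ROOT, Tissue.LEAF})
        assert r1.res == pytest.approx(r2.res, abs=1e-9)

    def test_max_over_stages_feeds_res(self):
        samples = [
            Sample(Tissue.INFLORESCENCE, "Z32", 200, 10**7, 1000),
            Sample(Tissue.INFLORESCENCE, "Z39", 500, 10**7, 1000),
            Sample(Tissue.INFLORESCENCE, "Z65", 300, 10**7, 1000),
            Sample(Tissue.ROOT, "s", 100, 10**7, 1000),
        ]
        r = res(ExpressionProfile("g", samples), Tissue.INFLORESCENCE, {Tissue.ROOT})
        # A = 50 (Z39 stage), B = 10 -> (50 - 10)/50
        assert r.res == pytest.approx(0.8)


def pearson_chi2_oracle(table):
    """Textbook Pearson statistic: sum over cells of (O - E)^2 / E."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestChiSquare:
    def test_identical_proportions(self):
        r = chi_square_diff(10, 1000, 10, 1000)
        assert r.statistic == 0 and r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_hand_computed_table(self):
        r = chi_square_diff(30, 1000, 10, 1000)
        want = pearson_chi2_oracle([[30, 970], [10, 990]])
        assert r.statistic == pytest.approx(want, abs=1e-8)
        assert r.df == 1 and r.significant

    def test_symmetric_in_samples(self):
        a = chi_square_diff(30, 1000, 10, 2000)
        b = chi_square_diff(10, 2000, 30, 1000)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_agrees_with_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            da, db = rng.integers(50, 5000, size=2)
            ca = int(rng.integers(1, da))
            cb = int(rng.integers(1, db))
            got = chi_square_diff(ca, int(da), cb, int(db)).statistic
            want = pearson_chi2_oracle([[ca, da - ca], [cb, db - cb]])
            assert got == pytest.approx(want, abs=1e-8)

    def test_significance_is_strictly_below_alpha(self):
        # alpha set exactly at the table's own p: strict <, so not significant
        r = chi_square_diff(30, 1000, 10, 1000)
        at_boundary = chi_square_diff(30, 1000, 10, 1000, alpha=r.p_value)
        assert not at_boundary.significant
        just_above = chi_square_diff(30, 1000, 10, 1000, alpha=r.p_value * 1.0001)
        assert just_above.significant

    def test_degenerate_zero_column(self):
        r = chi_square_diff(0, 1000, 0, 2000)
        assert r.statistic == 0 and r.p_value == 1.0 and not r.significant


class TestRelativeAbundance:
    def test_max_over_stages(self):
        values = {
            (Tissue.LEAF, "a"): 2.0,
            (Tissue.LEAF, "b"): 5.0,
            (Tissue.LEAF, "c"): 3.0,
        }
        out = relative_abundance(values, gene_set_mean=5.0)
        # tissue value 5 / mean 5 -> log2(1 + eps)
        assert out[Tissue.LEAF] == pytest.approx(math.log2(1.01))

    def test_gene_at_the_mean_maps_near_zero(self):
        out = relative_abundance({(Tissue.ROOT, "s"): 10.0}, gene_set_mean=10.0)
        assert out[Tissue.ROOT] == pytest.approx(0.0, abs=0.02)

    def test_zero_fpkm_hits_pseudocount_floor(self):
        out = relative_abundance({(Tissue.ROOT, "s"): 0.0}, gene_set_mean=3.0)
        assert out[Tissue.ROOT] == pytest.approx(math.log2(0.01))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance({(Tissue.ROOT, "s"): 1.0}, gene_set_mean=0.0)


class TestDdct:
    @pytest.mark.parametrize(
        "ddct, expected", [(0.0, 1.0), (-1.0, 2.0), (3.321928094887362, 0.1)]
    )
    def test_fold_change(self, ddct, expected):
        assert ddct_fold_change(ddct) == pytest.approx(expected, abs=1e-8)
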