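"""Library filter, pooling, and TSV round-trip behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estdigex.est_model_io import (
    ESTCountMatrix,
    ESTLibrary,
    NegativeCountError,
    Tier,
    TissueClass,
    UnknownTissueError,
    filter_libraries,
    pool_counts,
    read_count_matrix,
    read_expression_table,
    read_library_table,
    write_count_matrix,
    write_expression_table,
    write_library_table,
)


def lib(i, tissue=TissueClass.LEAF, total=5000, normalized=False):
    return ESTLibrary(f"lib{i}", tissue, total, normalized)


class TestFilterLibraries:
    @pytest.mark.parametrize(
        "totals, kept",
        [([999, 1000, 5000], [1000, 5000]), ([1], []), ([], [])],
    )
    def test_size_cutoff(self, totals, kept):
        libs = [lib(i, total=t) for i, t in enumerate(totals)]
        assert [l.est_total for l in filter_libraries(libs)] == kept

    def test_normalized_library_removed_regardless_of_size(self):
        libs = [lib(0, total=5000, normalized=True), lib(1, total=5000)]
        assert filter_libraries(libs) == [libs[1]]

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.booleans()).map(
                lambda t: ESTLibrary("x", TissueClass.ROOT, t[0], t[1])
            ),
            max_size=20,
        )
    )
    def test_idempotent(self, libs):
        once = filter_libraries(libs)
        assert filter_libraries(once) == once


class TestPoolCounts:
    def test_inflorescence_pool_is_additive(self, small_libraries):
        matrix = ESTCountMatrix(
            Tier.CONTIG_90,
            ["g1"],
            [l.library_id for l in small_libraries],
            np.array([[3, 7, 0, 0, 0]]),
        )
        pc = pool_counts(matrix, small_libraries, "g1")
        assert (pc.m, pc.M) == (10, 30000)

    def test_absent_gene_has_all_zero_matches(self, small_libraries):
        matrix = ESTCountMatrix(
            Tier.CONTIG_90,
            ["g1"],
            [l.library_id for l in small_libraries],
            np.zeros((1, 5), int),
        )
        pc = pool_counts(matrix, small_libraries, "g1")
        assert pc.m == 0 and all(n == 0 for n, _ in pc.per_pool.values())

    def test_pool_without_libraries_reported_empty(self, small_libraries):
        # the fixture has no stem library: the stem pool must exist with N=0
        matrix = ESTCountMatrix(
            Tier.CONTIG_90,
            ["g1"],
            [l.library_id for l in small_libraries],
            np.ones((1, 5), int),
        )
        pc = pool_counts(matrix, small_libraries, "g1")
        assert pc.per_pool[TissueClass.STEM] == (0, 0)

    def test_count_conservation_across_pools(self, small_libraries):
        counts = np.array([[2, 5, 1, 4, 3]])
        matrix = ESTCountMatrix(
            Tier.CONTIG_90, ["g1"], [l.library_id for l in small_libraries], counts
        )
        pc = pool_counts(matrix, small_libraries, "g1")
        assert pc.m + sum(n for n, _ in pc.per_pool.values()) == counts.sum()

    def test_invariant_to_library_order(self, small_libraries):
        counts = np.array([[2, 5, 1, 4, 3]])
        matrix = ESTCountMatrix(
            Tier.CONTIG_90, ["g1"], [l.library_id for l in small_libraries], counts
        )
        pc1 = pool_counts(matrix, small_libraries, "g1")
        pc2 = pool_counts(matrix, list(reversed(small_libraries)), "g1")
        assert (pc1.m, pc1.M, dict(pc1.per_pool)) == (pc2.m, pc2.M, dict(pc2.per_pool))

    def test_unknown_gene_and_missing_library_raise(self, small_libraries):
        matrix = ESTCountMatrix(
            Tier.CONTIG_90,
            ["g1"],
            [l.library_id for l in small_libraries],
            np.zeros((1, 5), int),
        )
        with pytest.raises(KeyError):
            pool_counts(matrix, small_libraries, "nope")
        with pytest.raises(Exception, match="missing from metadata"):
            pool_counts(matrix, small_libraries[:-1], "g1")


class TestRoundTrips:
    def test_count_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        matrix = ESTCountMatrix(
            Tier.CDS_99,
            ["g1", "g2", "g3"],
            ["a", "b", "c", "d"],
            rng.integers(0, 50, size=(3, 4)),
        )
        path = tmp_path / "m.tsv"
        write_count_matrix(path, matrix)
        assert read_count_matrix(path, Tier.CDS_99) == matrix

    def test_library_table_round_trip_and_alias(self, tmp_path):
        path = tmp_path / "libs.tsv"
        path.write_text(
            "library_id\ttissue\test_total\tnormalized\n"
            "L1\tanther\t5000\t0\n"
            "L2\troot\t3000\t1\n"
        )
        libs = read_library_table(path)
        assert libs[0].tissue_class is TissueClass.INFLORESCENCE
        assert libs[1].normalized_or_enriched is True
        out = tmp_path / "out.tsv"
        write_library_table(out, libs)
        assert read_library_table(out) == libs

    def test_unknown_tissue_alias_is_an_error(self, tmp_path):
        path = tmp_path / "libs.tsv"
        path.write_text(
            "library_id\ttissue\test_total\tnormalized\nL1\tmars-dust\t5000\t0\n"
        )
        with pytest.raises(UnknownTissueError, match="mars-dust"):
            read_library_table(path)

    def test_negative_count_names_the_cell(self):
        with pytest.raises(NegativeCountError, match="g2.*libB"):
            ESTCountMatrix(
                Tier.CONTIG_90,
                ["g1", "g2"],
                ["libA", "libB"],
                np.array([[1, 2], [3, -1]]),
            )

    def test_expression_table_round_trip(self, tmp_path):
        from estdigex.synthetic_data import archetype_rnaseq_design, generate_rnaseq

        profiles = generate_rnaseq(archetype_rnaseq_design(7, replicates=1, n_low_data=1))
        path = tmp_path / "expr.tsv"
        write_expression_table(path, profiles)
        back = read_expression_table(path)
        assert [p.gene_id for p in back] == [p.gene_id for p in profiles]
        assert back[0].samples == profiles[0].samples
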