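"""Merge/pool/collapse/exclude cascade and TU assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from astrx import reannotation as ra
from astrx.model import FeatureTable, StrandedCoverage, ValidationError

import oracles
from conftest import feat, make_table, random_feature_table


def spans(table: FeatureTable):
    return {(r.start, r.end, r.strand) for r in table.records}


def flat_coverage(length=10_000, depth=1):
    track = np.full(length, depth, dtype=np.int64)
    return StrandedCoverage(plus=track.copy(), minus=track.copy())


class TestMergeSameStrandOverlaps:
    def test_overlapping_pair_unions(self):
        out = ra.merge_same_strand_overlaps(
            make_table([feat("a", 100, 200), feat("b", 150, 300)])
        )
        assert spans(out) == {(100, 300, "+")}

    def test_opposite_strands_never_merge(self):
        out = ra.merge_same_strand_overlaps(
            make_table([feat("a", 100, 200, "+"), feat("b", 150, 300, "-")])
        )
        assert spans(out) == {(100, 200, "+"), (150, 300, "-")}

    def test_abutting_intervals_retained(self):
        # sharing zero positions: left for the gap rule, not overlap merging
        out = ra.merge_same_strand_overlaps(
            make_table([feat("a", 100, 200), feat("b", 201, 300)])
        )
        assert spans(out) == {(100, 200, "+"), (201, 300, "+")}

    def test_merged_metadata_unions(self):
        out = ra.merge_same_strand_overlaps(
            make_table(
                [feat("b", 150, 300, tps=(72,)), feat("a", 100, 200, tps=(48,))]
            )
        )
        (rec,) = out.records
        assert rec.id == "a|b"
        assert rec.timepoints == frozenset({48, 72})


class TestMergeWithinGap:
    def test_gap_15_merges_gap_16_does_not(self):
        merged = ra.merge_within_gap(
            make_table([feat("a", 100, 200), feat("b", 216, 300)])
        )
        assert spans(merged) == {(100, 300, "+")}
        kept = ra.merge_within_gap(
            make_table([feat("a", 100, 200), feat("b", 217, 300)])
        )
        assert spans(kept) == {(100, 200, "+"), (217, 300, "+")}

    def test_chain_merges_to_fixpoint(self):
        out = ra.merge_within_gap(
            make_table(
                [feat("a", 100, 200), feat("b", 211, 300), feat("c", 311, 400)]
            ),
            max_gap=10,
        )
        assert spans(out) == {(100, 400, "+")}

    def test_utr_type_wins_in_merge(self):
        out = ra.merge_within_gap(
            make_table([feat("a", 100, 200, ftype="UTR3"), feat("b", 205, 300)])
        )
        assert out.records[0].ftype == "UTR3"

    def test_negative_max_gap_rejected(self):
        with pytest.raises(ValueError):
            ra.merge_within_gap(make_table([feat("a", 1, 5)]), max_gap=-1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_fixpoint(self, seed):
        table = random_feature_table(np.random.default_rng(seed), n=30)
        assert spans(ra.merge_within_gap(table, 15)) == oracles.brute_merge_gap(
            table, 15
        )


class TestPoolWithUtrPriority:
    GENES = [feat("g1", 100, 510, "+", "gene")]

    def test_partial_overlap_trims_ncrna(self):
        out = ra.pool_with_utr_priority(
            make_table(self.GENES), make_table([feat("n1", 480, 520, "+")])
        )
        assert spans(out) == {(100, 510, "+"), (511, 520, "+")}

    def test_contained_ncrna_dropped(self):
        out = ra.pool_with_utr_priority(
            make_table(self.GENES), make_table([feat("n1", 480, 500, "+")])
        )
        assert spans(out) == {(100, 510, "+")}

    def test_opposite_strand_ncrna_untouched(self):
        out = ra.pool_with_utr_priority(
            make_table(self.GENES), make_table([feat("n1", 480, 520, "-")])
        )
        assert (480, 520, "-") in spans(out)

    def test_ncrna_spanning_gene_kept_as_two_segments(self):
        out = ra.pool_with_utr_priority(
            make_table([feat("g1", 200, 300, "+", "gene")]),
            make_table([feat("n1", 150, 350, "+")]),
        )
        assert spans(out) == {(200, 300, "+"), (150, 199, "+"), (301, 350, "+")}

    def test_gene_records_never_altered(self, rng):
        genes = random_feature_table(rng, 20, ncrna_frac=0.0, prefix="g")
        ncrnas = random_feature_table(rng, 20, ncrna_frac=1.0, prefix="n")
        out = ra.pool_with_utr_priority(genes, ncrnas)
        assert spans(genes) <= spans(out)


class TestCollapseByCoverage:
    def pair(self, gap):
        start = 1201 + gap
        return make_table([feat("a", 1000, 1200), feat("b", start, start + 299)])

    def test_covered_gap_300_collapses(self):
        out = ra.collapse_by_coverage(self.pair(300), flat_coverage())
        assert spans(out) == {(1000, 1800, "+")}

    def test_single_zero_depth_position_blocks(self):
        cov = flat_coverage()
        cov.plus[1350 - 1] = 0
        out = ra.collapse_by_coverage(self.pair(300), cov)
        assert len(out) == 2

    def test_gap_501_does_not_collapse_gap_500_does(self):
        assert len(ra.collapse_by_coverage(self.pair(501), flat_coverage())) == 2
        assert len(ra.collapse_by_coverage(self.pair(500), flat_coverage())) == 1

    def test_only_ncrna_records_collapse(self):
        table = make_table(
            [feat("a", 1000, 1200, ftype="gene"), feat("b", 1301, 1500)]
        )
        out = ra.collapse_by_coverage(table, flat_coverage())
        assert len(out) == 2

    def test_strand_matched_track_consulted(self):
        cov = flat_coverage()
        cov.minus[:] = 0
        table = make_table([feat("a", 1000, 1200, "-"), feat("b", 1301, 1500, "-")])
        assert len(ra.collapse_by_coverage(table, cov)) == 2

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_fixpoint(self, seed):
        rng = np.random.default_rng(seed)
        table = random_feature_table(rng, n=25, chromosome_length=5000)
        cov = StrandedCoverage(
            plus=(rng.random(5000) < 0.8).astype(np.int64),
            minus=(rng.random(5000) < 0.8).astype(np.int64),
        )
        out = ra.collapse_by_coverage(table, cov, max_gap=200)
        assert spans(out) == oracles.brute_collapse(table, cov, 200, 1)


class TestExcludeRepeatArtifacts:
    def test_overlap_fraction_at_threshold(self):
        table = make_table([feat("a", 101, 200)])  # length 100
        kept, excl = ra.exclude_repeat_artifacts(table, [(141, 260)])  # 60 nt inside
        assert len(excl) == 1 and len(kept) == 0

    def test_disjoint_ncrna_kept(self):
        table = make_table([feat("a", 101, 200)])
        kept, excl = ra.exclude_repeat_artifacts(table, [(500, 900)])
        assert len(kept) == 1 and len(excl) == 0

    def test_empty_repeat_list_excludes_nothing(self):
        table = make_table([feat("a", 101, 200)])
        kept, excl = ra.exclude_repeat_artifacts(table, [])
        assert len(kept) == 1 and len(excl) == 0

    def test_overlapping_repeats_counted_once(self):
        table = make_table([feat("a", 101, 200)])
        # two repeats covering the same 40 nt: union is 40 < 50 -> kept
        kept, excl = ra.exclude_repeat_artifacts(table, [(161, 200), (161, 200)])
        assert len(kept) == 1


class TestAssembleTus:
    def test_polycistronic_utr_arithmetic(self):
        pooled = make_table([feat("span", 100, 3000, "+", "gene")])
        genes = make_table(
            [
                feat("g1", 200, 900, "+", "gene"),
                feat("g2", 950, 1800, "+", "gene"),
                feat("g3", 1900, 2800, "+", "gene"),
            ]
        )
        (tu,) = ra.assemble_tus(pooled, genes)
        assert tu.kind == "polycistronic"
        assert tu.n_genes == 3
        assert (tu.utr5_len, tu.utr3_len) == (100, 200)
        assert tu.gene_ids == ("g1", "g2", "g3")

    def test_minus_strand_utr_and_gene_order(self):
        pooled = make_table([feat("span", 100, 1000, "-", "gene")])
        genes = make_table(
            [feat("g1", 150, 400, "-", "gene"), feat("g2", 500, 950, "-", "gene")]
        )
        (tu,) = ra.assemble_tus(pooled, genes)
        # 5' of a minus-strand unit is its right end
        assert (tu.utr5_len, tu.utr3_len) == (50, 50)
        assert tu.gene_ids == ("g2", "g1")

    def test_single_gene_is_monocistronic(self):
        pooled = make_table([feat("span", 100, 600, "+", "gene")])
        genes = make_table([feat("g1", 150, 550, "+", "gene")])
        (tu,) = ra.assemble_tus(pooled, genes)
        assert tu.kind == "monocistronic"

    def test_geneless_span_is_ncrna_unit(self):
        pooled = make_table([feat("span", 100, 300, "+", "ncRNA")])
        (tu,) = ra.assemble_tus(pooled, make_table([]))
        assert tu.kind == "ncRNA_unit"

    def test_overlapping_spans_rejected(self):
        pooled = make_table(
            [feat("s1", 100, 300, "+", "gene"), feat("s2", 250, 500, "+", "gene")]
        )
        with pytest.raises(ValidationError, match="overlap"):
            ra.assemble_tus(pooled, make_table([]))

    def test_orphan_genes_reported(self):
        pooled = make_table([feat("span", 100, 300, "+", "gene")])
        genes = make_table([feat("g1", 5000, 5500, "+", "gene")])
        tus, orphans = ra.assemble_tus(pooled, genes, return_orphans=True)
        assert orphans == ["g1"]


class TestGenomeFraction:
    def test_single_tu(self):
        from astrx.model import TranscriptionalUnit

        tu = TranscriptionalUnit(id="t", start=1, end=500, strand="+")
        assert ra.transcriptome_genome_fraction([tu], None, 1000) == 0.5

    def test_opposite_strand_overlap_counted_once(self):
        from astrx.model import TranscriptionalUnit

        tu = TranscriptionalUnit(id="t", start=1, end=500, strand="+")
        ncrnas = make_table([feat("n", 401, 600, "-")], length=1000)
        assert ra.transcriptome_genome_fraction([tu], ncrnas, 1000) == 0.6

    def test_no_features_gives_zero(self):
        assert ra.transcriptome_genome_fraction([], None, 1000) == 0.0


class TestNearestSameStrandDistance:
    def test_symmetric_gap(self):
        d = ra.nearest_same_strand_distance(
            make_table([feat("a", 100, 200), feat("b", 216, 300)])
        )
        assert d == {"a": 15, "b": 15}

    def test_overlapping_pair_distance_zero(self):
        d = ra.nearest_same_strand_distance(
            make_table([feat("a", 100, 200), feat("b", 150, 300)])
        )
        assert d == {"a": 0, "b": 0}

    def test_sole_feature_on_strand_undefined(self):
        d = ra.nearest_same_strand_distance(
            make_table([feat("a", 100, 200, "+"), feat("b", 300, 400, "-")])
        )
        assert d == {"a": None, "b": None}

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(10):
            table = random_feature_table(rng, n=50)
            assert ra.nearest_same_strand_distance(table) == oracles.brute_nearest(
                table
            )


class TestCascadeInvariants:
    def test_transcribed_positions_never_shrink_through_merging(self, rng):
        for _ in range(20):
            table = random_feature_table(rng, n=40)
            merged = ra.merge_within_gap(table, 15)
            positions_before = {
                (p, r.strand) for r in table.records for p in range(r.start, r.end + 1)
            }
            positions_after = {
                (p, r.strand)
                for r in merged.records
                for p in range(r.start, r.end + 1)
            }
            assert positions_before <= positions_after

    def test_no_mergeable_gap_remains_after_merge(self, rng):
        for _ in range(20):
            table = random_feature_table(rng, n=40)
            merged = ra.merge_within_gap(table, 15)
            for strand in ("+", "-"):
                recs = sorted(merged.on_strand(strand), key=lambda r: r.start)
                for a, b in zip(recs, recs[1:]):
                    assert b.start - a.end - 1 > 15

    def test_exclusion_never_increases_positions(self, rng):
        table = random_feature_table(rng, 30, ncrna_frac=1.0)
        kept, excluded = ra.exclude_repeat_artifacts(table, [(2000, 4000)])
        assert len(kept) + len(excluded) == len(table)
        assert spans(kept) <= spans(table)
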