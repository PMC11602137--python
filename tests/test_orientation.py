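"""Sense/antisense bin annotation against brute-force oracles and its invariants."""

import numpy as np
import pytest

from conftest import make_matrix, orientation_oracle, random_instance
from dsbdart.io_formats import GeneAnnotation, GenomicInterval, ValidationError
from dsbdart.orientation import (
    build_orientation_matrices,
    find_gene_flank_overlaps,
    orient,
)


def flip_genes(genes):
    return [GeneAnnotation(g.gene_id, g.interval.flipped()) for g in genes]


class TestOverlaps:
    def test_gene_outside_every_window_gives_no_record(self):
        sites = [GenomicInterval("chr1", 1000, 1001, name="s1")]
        genes = [GeneAnnotation("g1", GenomicInterval("chr1", 5000, 6000, "+"))]
        assert find_gene_flank_overlaps(sites, genes, flank=100) == []

    def test_gene_spanning_window_covers_all_bins(self):
        sites = [GenomicInterval("chr1", 1000, 1001, name="s1")]
        genes = [GeneAnnotation("g1", GenomicInterval("chr1", 0, 5000, "+"))]
        (ov,) = find_gene_flank_overlaps(sites, genes, flank=100)
        assert (ov.first_bin, ov.last_bin) == (0, 200)

    def test_partial_bin_counts_as_covered(self):
        sites = [GenomicInterval("chr1", 100, 101, name="s1")]
        # window [90,110), bins of 5; gene covers [97,103) -> bins 1..2 partially, bin index 1 and 2
        genes = [GeneAnnotation("g1", GenomicInterval("chr1", 97, 103, "+"))]
        (ov,) = find_gene_flank_overlaps(sites, genes, flank=10, bin_size=5)
        assert (ov.first_bin, ov.last_bin) == (1, 3)

    def test_matches_all_pairs_intersection_oracle(self, rng):
        for _ in range(30):
            sites, genes, _, _, flank = random_instance(rng, 5, 20)
            got = {
                (ov.site_id, ov.gene_id, ov.first_bin, ov.last_bin)
                for ov in find_gene_flank_overlaps(sites, genes, flank)
            }
            expected = set()
            for s in sites:
                a = (s.start + s.end) // 2
                for g in genes:
                    lo = max(g.interval.start, a - flank)
                    hi = min(g.interval.end, a + flank)
                    if lo < hi:
                        expected.add((s.name, g.gene_id, lo - (a - flank), hi - (a - flank)))
            assert got == expected


class TestBuildMatrices:
    def test_single_plus_gene_identity(self, rng):
        sites, _, plus, minus, flank = random_instance(rng, 1, 0)
        anchor = plus.anchors[0][1]
        genes = [GeneAnnotation("g1", GenomicInterval("chr1", max(0, anchor - flank),
                                                      anchor + flank, "+"))]
        res = orient(plus, minus, sites, genes)
        np.testing.assert_array_equal(res.sense_matrix.values, plus.values)
        np.testing.assert_array_equal(res.antisense_matrix.values, minus.values)

    def test_site_without_gene_is_excluded(self, rng):
        sites = [
            GenomicInterval("chr1", 1000, 1001, name="near"),
            GenomicInterval("chr1", 3000, 3001, name="lonely"),
        ]
        genes = [GeneAnnotation("g1", GenomicInterval("chr1", 950, 1100, "+"))]
        plus = make_matrix(rng.random((2, 200)), 100, site_ids=["near", "lonely"])
        minus = make_matrix(rng.random((2, 200)), 100, orientation="minus", site_ids=["near", "lonely"])
        res = orient(plus, minus, sites, genes)
        assert res.excluded_sites == ["lonely"]
        assert res.sense_matrix.site_ids == ["near"]

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(40):
            sites, genes, plus, minus, flank = random_instance(rng, 6, 10, 60)
            res = orient(plus, minus, sites, genes)
            sense, anti, excluded = orientation_oracle(sites, genes, plus, minus, flank)
            keep = [i for i, s in enumerate(sites) if s.name not in excluded]
            assert res.excluded_sites == [s.name for s in sites if s.name in excluded]
            np.testing.assert_allclose(res.sense_matrix.values, sense[keep], rtol=1e-12)
            np.testing.assert_allclose(res.antisense_matrix.values, anti[keep], rtol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        plus = make_matrix(rng.random((2, 20)), 10)
        minus = make_matrix(rng.random((2, 10)), 5, orientation="minus")
        with pytest.raises(ValidationError):
            build_orientation_matrices(plus, minus, [])

    def test_same_strand_nested_regions_counted_once(self, rng):
        # an isoform-style nested duplicate of the same gene region must not double-count
        sites = [GenomicInterval("chr1", 100, 101, name="s1")]
        plus = make_matrix(rng.random((1, 40)), 20)
        minus = make_matrix(rng.random((1, 40)), 20, orientation="minus")
        genes_one = [GeneAnnotation("g1", GenomicInterval("chr1", 80, 120, "+"))]
        genes_nested = genes_one + [GeneAnnotation("g1b", GenomicInterval("chr1", 90, 110, "+"))]
        res1 = orient(plus, minus, sites, genes_one)
        res2 = orient(plus, minus, sites, genes_nested)
        np.testing.assert_array_equal(res1.sense_matrix.values, res2.sense_matrix.values)

    def test_opposite_strand_overlap_contributes_to_both(self, rng):
        sites = [GenomicInterval("chr1", 100, 101, name="s1")]
        plus = make_matrix(rng.random((1, 40)), 20)
        minus = make_matrix(rng.random((1, 40)), 20, orientation="minus")
        genes = [
            GeneAnnotation("gp", GenomicInterval("chr1", 80, 120, "+")),
            GeneAnnotation("gm", GenomicInterval("chr1", 80, 120, "-")),
        ]
        res = orient(plus, minus, sites, genes)
        both = plus.values + minus.values
        np.testing.assert_allclose(res.sense_matrix.values, both, rtol=1e-12)
        np.testing.assert_allclose(res.antisense_matrix.values, both, rtol=1e-12)


class TestInvariants:
    def test_strand_swap_symmetry(self, rng):
        for _ in range(25):
            sites, genes, plus, minus, flank = random_instance(rng)
            res = orient(plus, minus, sites, genes)
            res_flip = orient(plus, minus, sites, flip_genes(genes))
            assert res.excluded_sites == res_flip.excluded_sites
            np.testing.assert_array_equal(res.sense_matrix.values,
                                          res_flip.antisense_matrix.values)
            np.testing.assert_array_equal(res.antisense_matrix.values,
                                          res_flip.sense_matrix.values)

    def test_single_cover_conservation(self, rng):
        # non-overlapping genes: sense + antisense == plus + minus on covered bins, 0 elsewhere
        for _ in range(20):
            flank = 50
            sites = [GenomicInterval("chr1", 500, 501, name="s1")]
            genes = []
            pos = 430
            j = 0
            while pos < 560:
                length = int(rng.integers(10, 30))
                genes.append(
                    GeneAnnotation(
                        f"g{j}",
                        GenomicInterval("chr1", pos, pos + length,
                                        "+" if rng.random() < 0.5 else "-"),
                    )
                )
                pos += length + int(rng.integers(1, 15))
                j += 1
            plus = make_matrix(rng.random((1, 2 * flank)), flank, site_ids=["s1"])
            minus = make_matrix(rng.random((1, 2 * flank)), flank, orientation="minus", site_ids=["s1"])
            plus.anchors = minus.anchors = [("chr1", 500)]
            res = orient(plus, minus, sites, genes)
            covered = np.zeros(2 * flank, dtype=bool)
            for g in genes:
                lo = max(g.interval.start, 450) - 450
                hi = min(g.interval.end, 550) - 450
                if lo < hi:
                    covered[lo:hi] = True
            total = res.sense_matrix.values[0] + res.antisense_matrix.values[0]
            np.testing.assert_allclose(
                total[covered], (plus.values + minus.values)[0][covered], rtol=1e-12
            )
            assert np.all(total[~covered] == 0)

    def test_adding_a_gene_never_decreases_bins(self, rng):
        for _ in range(15):
            sites, genes, plus, minus, flank = random_instance(rng, 5, 10)
            extra = GeneAnnotation(
                "extra", GenomicInterval("chr1", 0, 5000, "+" if rng.random() < 0.5 else "-")
            )
            res = orient(plus, minus, sites, genes)
            res_more = orient(plus, minus, sites, genes + [extra])
            keep = {sid: i for i, sid in enumerate(res_more.sense_matrix.site_ids)}
            for sid in res.sense_matrix.site_ids:
                i_more = keep[sid]
                i_old = res.sense_matrix.site_ids.index(sid)
                assert np.all(
                    res_more.sense_matrix.values[i_more]
                    >= res.sense_matrix.values[i_old] - 1e-12
                )
                assert np.all(
                    res_more.antisense_matrix.values[i_more]
                    >= res.antisense_matrix.values[i_old] - 1e-12
                )

    def test_gene_input_order_irrelevant(self, rng):
        sites, genes, plus, minus, flank = random_instance(rng, 8, 15)
        res = orient(plus, minus, sites, genes)
        res_rev = orient(plus, minus, sites, genes[::-1])
        np.testing.assert_array_equal(res.sense_matrix.values, res_rev.sense_matrix.values)
        np.testing.assert_array_equal(res.antisense_matrix.values,
                                      res_rev.antisense_matrix.values)
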