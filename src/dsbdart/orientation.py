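"""Sense/antisense annotation of flank-matrix bins relative to neighbouring gene orientation.

Around each DSB, nascent-RNA coverage on the plus strand is *sense* where it
falls inside a plus-strand gene region and *antisense* inside a minus-strand
gene region; minus-strand coverage is annotated with the mirrored logic. Only
bins lying within gene regions are used — a site whose flank overlaps no gene
cannot be classified and is removed.

One deliberate subtlety: a bin covered by two genes of *opposite* strand
contributes to both the sense and the antisense matrix (per-gene annotation
followed by summation), so sense + antisense can exceed plus + minus there.
Same-strand gene regions are merged per site before summation so that nested
isoform-style records do not double-count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .coverage import FlankMatrix, site_anchor, site_ids_for
from .io_formats import (
    STRAND_MINUS,
    STRAND_PLUS,
    GeneAnnotation,
    GenomicInterval,
    ValidationError,
)


@dataclass(frozen=True)
class GeneFlankOverlap:
    """Intersection of one gene region with one site's flank window, in bin indices.

    ``[first_bin, last_bin)`` is half-open; a bin partially covered by the gene
    counts as covered (any-overlap rule).
    """

    site_id: str
    gene_id: str
    gene_strand: str
    first_bin: int
    last_bin: int

    def __post_init__(self) -> None:
        if not 0 <= self.first_bin < self.last_bin:
            raise ValidationError(
                f"invalid bin range [{self.first_bin}, {self.last_bin}) for "
                f"site {self.site_id} / gene {self.gene_id}"
            )


@dataclass
class OrientationResult:
    """Sense and antisense flank matrices plus the site ids removed for lack of genes."""

    sense_matrix: FlankMatrix
    antisense_matrix: FlankMatrix
    excluded_sites: list[str]


def find_gene_flank_overlaps(
    sites: Sequence[GenomicInterval],
    genes: Iterable[GeneAnnotation],
    flank: int = 2500,
    bin_size: int = 1,
) -> list[GeneFlankOverlap]:
    """Intersect gene regions with each site's ``[anchor - flank, anchor + flank)`` window.

    Returns one record per (site, gene) pair with a non-empty intersection,
    converted to bin indices (bedtools-intersect-style, then binned).
    """
    genes = list(genes)
    n_bins = 2 * flank // bin_size
    ids = site_ids_for(sites)
    out: list[GeneFlankOverlap] = []
    for sid, site in zip(ids, sites):
        anchor = site_anchor(site)
        w_start, w_end = anchor - flank, anchor + flank
        for gene in genes:
            g = gene.interval
            if g.chrom != site.chrom:
                continue
            lo, hi = max(g.start, w_start), min(g.end, w_end)
            if lo >= hi:
                continue
            first_bin = (lo - w_start) // bin_size
            last_bin = -((w_start - hi) // bin_size)  # ceil division
            out.append(
                GeneFlankOverlap(sid, gene.gene_id, g.strand, first_bin, min(last_bin, n_bins))
            )
    return out


def _merged_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open bin ranges."""
    merged: list[list[int]] = []
    for lo, hi in sorted(ranges):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def build_orientation_matrices(
    plus: FlankMatrix,
    minus: FlankMatrix,
    overlaps: Iterable[GeneFlankOverlap],
) -> OrientationResult:
    """Reorganize plus/minus flank matrices into sense/antisense matrices.

    For every gene region overlapping a site's flank: the plus-strand coverage
    over its bins goes to sense if the gene is on ``+`` (antisense otherwise),
    and the minus-strand coverage goes to sense if the gene is on ``-``
    (antisense otherwise). Contributions from multiple gene regions at one
    site are summed per bin — for sense and antisense alike — after merging
    same-strand regions. Bins outside every gene region are 0 in both outputs.
    Sites with no overlapping gene are dropped from both matrices and listed
    in ``excluded_sites``.
    """
    if not plus.same_shape_as(minus):
        raise ValidationError("plus and minus matrices differ in sites, flank or bin size")
    n_sites, n_bins = plus.values.shape
    index = {sid: i for i, sid in enumerate(plus.site_ids)}

    # site -> strand -> list of bin ranges
    per_site: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ov in overlaps:
        if ov.site_id not in index:
            raise ValidationError(f"overlap references unknown site {ov.site_id!r}")
        if ov.last_bin > n_bins:
            raise ValidationError(f"overlap bin range exceeds matrix width for {ov.site_id}")
        per_site.setdefault(ov.site_id, {STRAND_PLUS: [], STRAND_MINUS: []})[
            ov.gene_strand
        ].append((ov.first_bin, ov.last_bin))

    sense = np.zeros_like(plus.values)
    antisense = np.zeros_like(plus.values)
    for sid, by_strand in per_site.items():
        i = index[sid]
        for lo, hi in _merged_ranges(by_strand[STRAND_PLUS]):
            sense[i, lo:hi] += plus.values[i, lo:hi]
            antisense[i, lo:hi] += minus.values[i, lo:hi]
        for lo, hi in _merged_ranges(by_strand[STRAND_MINUS]):
            sense[i, lo:hi] += minus.values[i, lo:hi]
            antisense[i, lo:hi] += plus.values[i, lo:hi]

    keep = [i for i, sid in enumerate(plus.site_ids) if sid in per_site]
    excluded = [sid for sid in plus.site_ids if sid not in per_site]

    def _make(values: np.ndarray, orientation: str) -> FlankMatrix:
        return FlankMatrix(
            site_ids=[plus.site_ids[i] for i in keep],
            anchors=[plus.anchors[i] for i in keep],
            flank=plus.flank,
            bin_size=plus.bin_size,
            orientation=orientation,
            values=values[keep],
            clipped=plus.clipped[keep],
        )

    return OrientationResult(
        sense_matrix=_make(sense, "sense"),
        antisense_matrix=_make(antisense, "antisense"),
        excluded_sites=excluded,
    )


def orient(
    plus: FlankMatrix,
    minus: FlankMatrix,
    sites: Sequence[GenomicInterval],
    genes: Iterable[GeneAnnotation],
) -> OrientationResult:
    """Convenience wrapper: intersect genes with flanks, then build sense/antisense."""
    overlaps = find_gene_flank_overlaps(sites, list(genes), plus.flank, plus.bin_size)
    return build_orientation_matrices(plus, minus, overlaps)
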