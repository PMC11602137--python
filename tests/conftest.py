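"""Shared fixtures and brute-force oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dsbdart.coverage import FlankMatrix
from dsbdart.io_formats import GeneAnnotation, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, flank, bin_size=1, orientation="plus", site_ids=None, chrom="chr1"):
    """FlankMatrix from a raw 2D array with synthetic anchors."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if site_ids is None:
        site_ids = [f"s{i + 1}" for i in range(n)]
    anchors = [(chrom, 10_000 + 10_000 * i) for i in range(n)]
    return FlankMatrix(
        site_ids=list(site_ids),
        anchors=anchors,
        flank=flank,
        bin_size=bin_size,
        orientation=orientation,
        values=values,
    )


def random_instance(rng, n_sites_max=10, n_genes_max=20, flank_max=200, chrom_len=5_000):
    """A random orientation problem: sites, genes, and plus/minus matrices on one chromosome.

    Anchors are kept a full flank from the chromosome ends so windows never clip.
    """
    flank = int(rng.integers(10, flank_max + 1))
    n_sites = int(rng.integers(1, n_sites_max + 1))
    n_genes = int(rng.integers(0, n_genes_max + 1))
    sites = []
    for i in range(n_sites):
        anchor = int(rng.integers(flank, chrom_len - flank))
        sites.append(GenomicInterval("chr1", anchor, anchor + 1, name=f"s{i + 1}"))
    genes = []
    for j in range(n_genes):
        start = int(rng.integers(0, chrom_len - 10))
        length = int(rng.integers(1, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(f"g{j + 1}", GenomicInterval("chr1", start, start + length, strand))
        )
    n_bins = 2 * flank
    plus = make_matrix(rng.random((n_sites, n_bins)), flank, 1, "plus",
                       [s.name for s in sites])
    minus = make_matrix(rng.random((n_sites, n_bins)), flank, 1, "minus",
                        [s.name for s in sites])
    # anchors must match the sites so overlap bin ranges line up
    plus.anchors = [(s.chrom, (s.start + s.end) // 2) for s in sites]
    minus.anchors = list(plus.anchors)
    return sites, genes, plus, minus, flank


def orientation_oracle(sites, genes, plus, minus, flank, bin_size=1):
    """Brute-force sense/antisense construction looping over every (site, bin, gene) triple.

    Mirrors the contract: per strand, a bin is covered if any gene of that
    strand overlaps it (union of same-strand regions — merged, so no
    double-count within a strand); covered bins take the same-strand track
    into sense and the opposite track into antisense; a site with no covered
    bin on either strand is excluded.
    """
    n_bins = 2 * flank // bin_size
    sense = np.zeros_like(plus.values)
    anti = np.zeros_like(minus.values)
    excluded = []
    for i, site in enumerate(sites):
        anchor = (site.start + site.end) // 2
        w_start = anchor - flank
        any_cover = False
        for strand, same, opp in (("+", plus, minus), ("-", minus, plus)):
            for b in range(n_bins):
                bin_lo = w_start + b * bin_size
                bin_hi = bin_lo + bin_size
                covered = False
                for g in genes:
                    if g.interval.chrom != site.chrom or g.strand != strand:
                        continue
                    if g.interval.start < bin_hi and g.interval.end > bin_lo:
                        covered = True
                        break
                if covered:
                    any_cover = True
                    sense[i, b] += same.values[i, b]
                    anti[i, b] += opp.values[i, b]
        if not any_cover:
            excluded.append(site.name)
    return sense, anti, excluded


def pileup_oracle(reads, chrom_len, strand, scale):
    """Naive nested-loop per-base pileup for one chromosome and strand."""
    out = np.zeros(chrom_len)
    for r in reads:
        if r.strand != strand:
            continue
        for p in range(r.start, r.end):
            out[p] += scale
    return out


def ranksum_enumeration_p(x, y):
    """Two-sided exact rank-sum p by full enumeration of label assignments (tie-free)."""
    from itertools import combinations

    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    for rank, i in enumerate(order, 1):
        ranks[i] = float(rank)
    n, m = len(x), len(y)
    u_obs = sum(ranks[:n]) - n * (n + 1) / 2
    center = n * m / 2
    total = extreme = 0
    for comb in combinations(range(n + m), n):
        u = sum(ranks[i] for i in comb) - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return extreme / total
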