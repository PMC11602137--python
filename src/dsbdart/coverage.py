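"""Transcript-strand assignment, CPM per-base coverage, and DSB-anchored flank matrices.

The central objects are :class:`StrandedCoverage` — per-chromosome, per-strand
arrays of CPM-normalized per-base read depth — and :class:`FlankMatrix`, a
sites x bins array of that coverage in a fixed window around each DSB anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    STRAND_MINUS,
    STRAND_NONE,
    STRAND_PLUS,
    AlignedSegment,
    ChromSizes,
    GenomicInterval,
    ValidationError,
    write_bedgraph,
)

logger = logging.getLogger(__name__)

PROTOCOLS = ("forward", "reverse")


@dataclass
class StrandedReadSet:
    """Stranded read intervals plus the library size used for CPM normalization.

    ``library_size`` may exceed ``len(reads)``: it is the total read count of the
    library, of which the retained reads may cover only a region of interest.
    """

    reads: list[GenomicInterval]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < len(self.reads):
            raise ValidationError(
                f"library_size {self.library_size} < number of reads {len(self.reads)}"
            )
        for r in self.reads:
            if r.strand == STRAND_NONE:
                raise ValidationError(f"unstranded read {r.chrom}:{r.start}-{r.end}")

    def strand_counts(self) -> dict[str, int]:
        counts = {STRAND_PLUS: 0, STRAND_MINUS: 0}
        for r in self.reads:
            counts[r.strand] += 1
        return counts

    def subset(self, strand: str) -> list[GenomicInterval]:
        return [r for r in self.reads if r.strand == strand]


def _flip(strand: str) -> str:
    return STRAND_MINUS if strand == STRAND_PLUS else STRAND_PLUS


def assign_transcript_strand(
    alignments: Iterable[AlignedSegment | GenomicInterval],
    protocol: str,
    library_size: int | None = None,
) -> StrandedReadSet:
    """Assign each alignment a transcript strand under a stranded-library protocol.

    ``reverse`` is the dUTP-type contract (TruSeq stranded kits): a single-end or
    first-of-pair alignment on ``+`` transcribes the ``-`` strand and vice versa,
    while second-of-pair orientation is preserved. ``forward`` is the identity.
    Unstranded alignments are skipped with a logged count. The split into
    plus-strand and minus-strand read files mirrors the samtools-based strand
    separation step of stranded RNA-seq pipelines.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    reads: list[GenomicInterval] = []
    skipped = 0
    for aln in alignments:
        if isinstance(aln, GenomicInterval):
            aln = AlignedSegment(aln.chrom, aln.start, aln.end, aln.strand, mate=1)
        if aln.strand == STRAND_NONE:
            skipped += 1
            continue
        if protocol == "forward" or aln.mate == 2:
            strand = aln.strand
        else:
            strand = _flip(aln.strand)
        reads.append(GenomicInterval(aln.chrom, aln.start, aln.end, strand))
    if skipped:
        logger.warning("assign_transcript_strand: skipped %d unstranded alignments", skipped)
    counts = {STRAND_PLUS: 0, STRAND_MINUS: 0}
    for r in reads:
        counts[r.strand] += 1
    logger.info(
        "assign_transcript_strand(protocol=%s): %d plus / %d minus reads",
        protocol,
        counts[STRAND_PLUS],
        counts[STRAND_MINUS],
    )
    return StrandedReadSet(reads, library_size if library_size is not None else len(reads))


@dataclass
class StrandedCoverage:
    """CPM-normalized per-base depth, one array per (chromosome, strand).

    The normalization constant is ``10^6 / library_size``; position ``p`` on
    strand ``s`` holds ``(reads on s covering p) * 10^6 / library_size``.
    """

    sizes: ChromSizes
    library_size: int
    data: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def scale(self) -> float:
        return 1e6 / self.library_size

    def get(self, chrom: str, strand: str) -> np.ndarray:
        per_strand = self.data.get(strand, {})
        if chrom in per_strand:
            return per_strand[chrom]
        return np.zeros(self.sizes[chrom], dtype=float)

    def total(self, chrom: str) -> np.ndarray:
        return self.get(chrom, STRAND_PLUS) + self.get(chrom, STRAND_MINUS)

    def track(self, chrom: str, strand_of_track: str) -> np.ndarray:
        if strand_of_track == "plus":
            return self.get(chrom, STRAND_PLUS)
        if strand_of_track == "minus":
            return self.get(chrom, STRAND_MINUS)
        if strand_of_track == "unstranded":
            return self.total(chrom)
        raise ValueError(f"unknown track strand {strand_of_track!r}")

    def to_bedgraph(self, path, strand: str) -> None:
        write_bedgraph(self.data.get(strand, {}), path)


def cpm_coverage(reads: StrandedReadSet, sizes: ChromSizes) -> StrandedCoverage:
    """Build CPM per-base coverage from a stranded read set.

    Coverage counts full read spans. Duplicating every read (with the library
    size scaling accordingly) leaves the values unchanged.
    """
    if reads.library_size <= 0:
        raise ValidationError("library_size must be > 0 for CPM normalization")
    scale = 1e6 / reads.library_size
    # Group read endpoints per (strand, chromosome), then difference-array pileup:
    # +1 at each read start, -1 at each end, cumulative sum gives depth.
    grouped: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    for r in reads.reads:
        if r.chrom not in sizes:
            raise ValidationError(f"read out of bounds: unknown chromosome {r.chrom!r}")
        starts_ends = grouped.setdefault((r.strand, r.chrom), ([], []))
        starts_ends[0].append(r.start)
        starts_ends[1].append(r.end)
    data: dict[str, dict[str, np.ndarray]] = {STRAND_PLUS: {}, STRAND_MINUS: {}}
    for (strand, chrom), (starts, ends) in grouped.items():
        length = sizes[chrom]
        ends_arr = np.asarray(ends, dtype=np.int64)
        starts_arr = np.asarray(starts, dtype=np.int64)
        if ends_arr.max() > length:
            i = int(np.argmax(ends_arr > length))
            raise ValidationError(
                f"read out of bounds: {chrom}:{starts[i]}-{ends[i]} exceeds "
                f"chromosome length {length}"
            )
        diff = np.zeros(length + 1, dtype=float)
        np.add.at(diff, starts_arr, 1.0)
        np.add.at(diff, ends_arr, -1.0)
        data[strand][chrom] = np.cumsum(diff[:-1]) * scale
    return StrandedCoverage(sizes=sizes, library_size=reads.library_size, data=data)


ORIENTATIONS = ("plus", "minus", "sense", "antisense", "total")


@dataclass
class FlankMatrix:
    """Sites x bins CPM coverage anchored at DSB midpoints.

    Bins run left to right in genomic coordinates over ``[anchor - flank,
    anchor + flank)``; each bin value is the mean per-base CPM over its
    ``bin_size`` bases. ``clipped`` flags rows whose window ran off a
    chromosome end (those positions contribute 0).
    """

    site_ids: list[str]
    anchors: list[tuple[str, int]]
    flank: int
    bin_size: int
    orientation: str
    values: np.ndarray
    clipped: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.bin_size < 1 or (2 * self.flank) % self.bin_size:
            raise ValidationError("bin_size must be >=1 and divide 2*flank")
        n_bins = 2 * self.flank // self.bin_size
        if self.values.shape != (len(self.site_ids), n_bins):
            raise ValidationError(
                f"values shape {self.values.shape} != ({len(self.site_ids)}, {n_bins})"
            )
        if len(self.anchors) != len(self.site_ids):
            raise ValidationError("anchors and site_ids differ in length")
        if self.clipped is None:
            self.clipped = np.zeros(len(self.site_ids), dtype=bool)
        self.clipped = np.asarray(self.clipped, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row(self, site_id: str) -> np.ndarray:
        return self.values[self.site_ids.index(site_id)]

    def subset(self, site_subset: Sequence[str]) -> "FlankMatrix":
        index = {sid: i for i, sid in enumerate(self.site_ids)}
        missing = [s for s in site_subset if s not in index]
        if missing:
            raise ValidationError(f"unknown site ids {missing}")
        rows = [index[s] for s in site_subset]
        return FlankMatrix(
            site_ids=list(site_subset),
            anchors=[self.anchors[i] for i in rows],
            flank=self.flank,
            bin_size=self.bin_size,
            orientation=self.orientation,
            values=self.values[rows],
            clipped=self.clipped[rows],
        )

    def same_shape_as(self, other: "FlankMatrix") -> bool:
        return (
            self.site_ids == other.site_ids
            and self.flank == other.flank
            and self.bin_size == other.bin_size
        )


def site_anchor(site: GenomicInterval) -> int:
    """DSB anchor base of a site interval (floor midpoint; symmetric for the 8-bp motif)."""
    return site.midpoint


def _site_id(site: GenomicInterval, index: int) -> str:
    return site.name if site.name not in (".", "") else f"site_{index + 1}"


def site_ids_for(sites: Sequence[GenomicInterval]) -> list[str]:
    return [_site_id(s, i) for i, s in enumerate(sites)]


def compute_flank_matrix(
    cov: StrandedCoverage,
    sites: Sequence[GenomicInterval],
    flank: int = 2500,
    bin_size: int = 1,
    strand_of_track: str = "unstranded",
) -> FlankMatrix:
    """Extract the sites x bins coverage matrix around DSB anchors.

    The defaults (2.5 kb flanks, 1 bp bins) give the 5000-column per-site
    matrix used for metagene analysis. Windows are genomic-left-to-right;
    DSB sites are unstranded anchors, so rows are never flipped. Window
    positions outside the chromosome contribute 0 and flag the row as clipped.
    """
    if flank <= 0:
        raise ValidationError("flank must be > 0")
    n_bins = 2 * flank // bin_size
    if bin_size < 1 or 2 * flank != n_bins * bin_size:
        raise ValidationError("bin_size must be >=1 and divide 2*flank")
    ids = site_ids_for(sites)
    anchors = [(s.chrom, site_anchor(s)) for s in sites]
    values = np.zeros((len(sites), n_bins), dtype=float)
    clipped = np.zeros(len(sites), dtype=bool)
    for i, (chrom, anchor) in enumerate(anchors):
        arr = cov.track(chrom, strand_of_track)
        w_start, w_end = anchor - flank, anchor + flank
        window = np.zeros(2 * flank, dtype=float)
        lo, hi = max(w_start, 0), min(w_end, arr.size)
        if lo >= hi:
            clipped[i] = True
            logger.warning(
                "site %s window [%d, %d) lies entirely off chromosome %s",
                ids[i], w_start, w_end, chrom,
            )
        else:
            window[lo - w_start : hi - w_start] = arr[lo:hi]
            if w_start < 0 or w_end > arr.size:
                clipped[i] = True
        values[i] = window.reshape(n_bins, bin_size).mean(axis=1)
    return FlankMatrix(
        site_ids=ids,
        anchors=anchors,
        flank=flank,
        bin_size=bin_size,
        orientation=strand_of_track if strand_of_track in ORIENTATIONS else "total",
        values=values,
        clipped=clipped,
    )
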