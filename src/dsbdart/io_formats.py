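"""Genomic interval types and readers/writers for the plain-text formats the pipeline touches.

All coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
GTF input (1-based, closed) is converted on read. Chromosome names are passed
through verbatim — no ``chr`` prefix normalization is ever applied; use
:func:`check_chrom_namespaces` to detect name-set disagreement between inputs
before running an analysis.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_VALID_STRANDS = frozenset({STRAND_PLUS, STRAND_MINUS, STRAND_NONE})


class ParseError(ValueError):
    """A malformed line in an input file; the message names the file and line number."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a contract (empty interval, bad strand, ...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE
    name: str = "."
    score: str = "0"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """DSB anchor convention: floor of the interval midpoint.

        Site intervals wider than 1 bp (e.g. the 8-bp AsiSI recognition motif)
        are anchored at this base.
        """
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom and self.start < other.end and other.start < self.end
        )

    def flipped(self) -> "GenomicInterval":
        if self.strand == STRAND_NONE:
            return self
        flip = STRAND_MINUS if self.strand == STRAND_PLUS else STRAND_PLUS
        return replace(self, strand=flip)


@dataclass(frozen=True)
class GeneAnnotation:
    """A stranded gene region used for sense/antisense orientation calls."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand == STRAND_NONE:
            raise ValidationError(f"gene {self.gene_id!r} is unstranded")

    @property
    def strand(self) -> str:
        return self.interval.strand


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, mapping=None, **kwargs):
        super().__init__(mapping or {}, **kwargs)
        for chrom, length in self.items():
            if int(length) <= 0:
                raise ValidationError(f"non-positive length for chromosome {chrom!r}")

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self:
            raise ValidationError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length "
                f"{self[iv.chrom]}"
            )

    @classmethod
    def read(cls, path) -> "ChromSizes":
        sizes = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
                try:
                    sizes[fields[0]] = int(fields[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: length not an integer") from exc
        return cls(sizes)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.items():
                fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# BED6


def read_intervals(path, require_strand: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into a list of :class:`GenomicInterval` (file order).

    The BED half-open convention is preserved verbatim. Rows with fewer than
    six columns yield unstranded intervals unless ``require_strand`` is set,
    in which case a missing strand column is a :class:`ValidationError`.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: coordinates not integers") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else STRAND_NONE
            if strand not in _VALID_STRANDS:
                raise ParseError(f"{path}:{lineno}: invalid strand field {strand!r}")
            if require_strand and strand == STRAND_NONE:
                raise ValidationError(f"{path}:{lineno}: strand required but missing")
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, strand, name=name, score=score)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6 (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene annotation (BED6 or GTF)

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_annotation(path, dialect: str | None = None) -> list[GeneAnnotation]:
    """Read gene regions from BED6 or GTF.

    ``dialect`` is ``'bed'``, ``'gtf'`` or None (sniffed from the extension).
    GTF ``gene`` features (1-based closed coordinates) are converted to the
    internal 0-based half-open convention. Unstranded genes and duplicate
    gene_ids are rejected.
    """
    if dialect is None:
        dialect = "gtf" if str(path).endswith((".gtf", ".gff")) else "bed"
    if dialect == "bed":
        genes = []
        for iv in read_intervals(path, require_strand=True):
            genes.append(GeneAnnotation(iv.name, iv))
    elif dialect == "gtf":
        genes = list(_read_gtf_genes(path))
    else:
        raise ValidationError(f"unknown annotation dialect {dialect!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _read_gtf_genes(path) -> Iterator[GeneAnnotation]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated GTF fields")
            if fields[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(fields[8])
            if not m:
                raise ParseError(f"{path}:{lineno}: gene feature lacks gene_id attribute")
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: coordinates not integers") from exc
            strand = fields[6]
            if strand not in (STRAND_PLUS, STRAND_MINUS):
                raise ValidationError(f"{path}:{lineno}: gene {m.group(1)!r} is unstranded")
            # GTF is 1-based inclusive; internal convention is 0-based half-open.
            yield GeneAnnotation(
                m.group(1),
                GenomicInterval(fields[0], start1 - 1, end1, strand, name=m.group(1)),
            )


def write_gene_annotation_gtf(genes: Iterable[GeneAnnotation], path, source="dsbdart") -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


def check_chrom_namespaces(*named_sets: tuple[str, Iterable[str]]) -> list[str]:
    """Preflight check: report chromosome-name-set disagreement between inputs.

    Takes ``(label, chrom_names)`` pairs; returns human-readable warnings (empty
    when every input shares one namespace). Names are compared verbatim.
    """
    sets = [(label, set(names)) for label, names in named_sets]
    warnings = []
    for i, (label_a, a) in enumerate(sets):
        for label_b, b in sets[i + 1 :]:
            only_a, only_b = sorted(a - b), sorted(b - a)
            if only_a or only_b:
                warnings.append(
                    f"chromosome namespaces differ between {label_a} and {label_b}: "
                    f"only in {label_a}: {only_a or '-'}; only in {label_b}: {only_b or '-'}"
                )
    return warnings


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(values_by_chrom: dict[str, np.ndarray], path) -> None:
    """Write per-base values as run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom, arr in values_by_chrom.items():
            arr = np.asarray(arr)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


def read_bedgraph(path, sizes: ChromSizes) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-base arrays over ``sizes`` (missing spans = 0)."""
    out = {chrom: np.zeros(length, dtype=float) for chrom, length in sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in out:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if e > sizes[chrom]:
                raise ValidationError(f"{path}:{lineno}: span exceeds chromosome length")
            out[chrom][s:e] = v
    return out


# ---------------------------------------------------------------------------
# Flank matrix TSV with metadata sidecar header


def write_flank_matrix(matrix, path) -> None:
    """Persist a FlankMatrix as TSV: a ``# meta:`` JSON header line, then a header
    row of signed bin-start offsets and one row per site. Values are written with
    17 significant digits so read-back reproduces them to full float64 precision.
    """
    n_sites, n_bins = matrix.values.shape
    if len(matrix.site_ids) != n_sites or n_bins != 2 * matrix.flank // matrix.bin_size:
        raise ValidationError("matrix metadata inconsistent with value shape")
    meta = {
        "flank": matrix.flank,
        "bin_size": matrix.bin_size,
        "orientation": matrix.orientation,
        "anchors": [[c, int(p)] for c, p in matrix.anchors],
        "clipped": [bool(x) for x in matrix.clipped],
    }
    offsets = [-matrix.flank + j * matrix.bin_size for j in range(n_bins)]
    with open(path, "w") as fh:
        fh.write("# meta: " + json.dumps(meta, separators=(",", ":")) + "\n")
        fh.write("site_id\t" + "\t".join(str(o) for o in offsets) + "\n")
        for sid, row in zip(matrix.site_ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_flank_matrix(path):
    """Inverse of :func:`write_flank_matrix`."""
    from .coverage import FlankMatrix  # deferred: coverage imports this module

    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# meta: "):
            raise ParseError(f"{path}:1: missing '# meta:' header line")
        meta = json.loads(first[len("# meta: ") :])
        header = fh.readline().rstrip("\n").split("\t")
        n_bins = len(header) - 1
        site_ids, rows = [], []
        for lineno, line in enumerate(fh, 3):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_bins + 1:
                raise ValidationError(
                    f"{path}:{lineno}: row length {len(fields) - 1} != {n_bins} bins"
                )
            site_ids.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
    values = np.array(rows, dtype=float).reshape(len(site_ids), n_bins)
    return FlankMatrix(
        site_ids=site_ids,
        anchors=[(c, int(p)) for c, p in meta["anchors"]],
        flank=int(meta["flank"]),
        bin_size=int(meta["bin_size"]),
        orientation=meta["orientation"],
        values=values,
        clipped=np.array(meta.get("clipped", [False] * len(site_ids)), dtype=bool),
    )


# ---------------------------------------------------------------------------
# FASTA and SAM adapters


def read_fasta(path) -> dict[str, str]:
    """Read sequences from FASTA keyed by record name (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


@dataclass(frozen=True)
class AlignedSegment:
    """Minimal stranded alignment record fed to transcript-strand assignment.

    ``mate`` is 1 for single-end or first-of-pair, 2 for second-of-pair.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mate: int = 1


def read_sam_alignments(path) -> list[AlignedSegment]:
    """Optional SAM/BAM adapter (pysam); yields the same contract as BED reads.

    Only aligned blocks are spanned (reference_start..reference_end of the primary
    alignment); unmapped, secondary and supplementary records are skipped.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = STRAND_MINUS if rec.is_reverse else STRAND_PLUS
            mate = 2 if (rec.is_paired and rec.is_read2) else 1
            out.append(
                AlignedSegment(
                    rec.reference_name, rec.reference_start, rec.reference_end, strand, mate
                )
            )
    return out
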