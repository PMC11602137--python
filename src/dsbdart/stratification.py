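"""Stratify DSB sites by cleavage efficiency, repair-pathway propensity and transcription.

Site labels live in a :class:`pandas.DataFrame` (the "site table") indexed by
site_id with columns::

    chrom, anchor, cut_status, cleavage_reads, efficiency_rank,
    pathway, pathway_ratio, transcription_class

Cleavage efficiency follows the DSB-capture convention: raw read counts in a
+/- 500 bp window around the anchor, sites ordered by count. Repair-pathway
propensity is the ratio of RAD51 coverage (anchor +/- 4 kb) to XRCC4 coverage
(anchor +/- 1 kb); the top-k ratios are labelled HR-prone and the bottom-k
NHEJ-prone. The transcription class splits sites by their total sense CPM in
a baseline (undamaged) condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import FlankMatrix, StrandedCoverage, StrandedReadSet, site_anchor, site_ids_for
from .io_formats import GenomicInterval, ValidationError

logger = logging.getLogger(__name__)

ASISI_MOTIF = "GCGATCGC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def new_site_table(sites: Sequence[GenomicInterval], cut_status=None) -> pd.DataFrame:
    """Initialize a site table from site intervals (anchor = interval midpoint)."""
    if len(sites) == 0:
        raise ValidationError("empty site list")
    ids = site_ids_for(sites)
    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "anchor": [site_anchor(s) for s in sites],
            "cut_status": cut_status if cut_status is not None else "cut",
            "cleavage_reads": np.nan,
            "efficiency_rank": np.nan,
            "pathway": "unlabelled",
            "pathway_ratio": np.nan,
            "transcription_class": "unlabelled",
        },
        index=pd.Index(ids, name="site_id"),
    )
    return table


def _reads_as_arrays(reads) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    intervals = reads.reads if isinstance(reads, StrandedReadSet) else list(reads)
    chroms = np.array([r.chrom for r in intervals])
    starts = np.array([r.start for r in intervals], dtype=int)
    ends = np.array([r.end for r in intervals], dtype=int)
    return chroms, starts, ends


def rank_cleavage_efficiency(
    dsb_reads,
    sites: Sequence[GenomicInterval],
    window: int = 500,
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count DSB-capture reads in ``[anchor - window, anchor + window)`` and rank sites.

    Ranks ascend with read count (rank 1 = fewest reads = least efficiently
    cut); ties are broken by site_id lexicographic order, a stable documented
    choice. Counts are raw reads, not CPM.
    """
    if window <= 0:
        raise ValidationError("window must be > 0")
    if table is None:
        table = new_site_table(sites)
    chroms, starts, ends = _reads_as_arrays(dsb_reads)
    counts = []
    for sid, row in table.iterrows():
        lo, hi = row["anchor"] - window, row["anchor"] + window
        if chroms.size:
            mask = (chroms == row["chrom"]) & (starts < hi) & (ends > lo)
            counts.append(int(mask.sum()))
        else:
            counts.append(0)
    table = table.copy()
    table["cleavage_reads"] = counts
    order = sorted(table.index, key=lambda sid: (table.at[sid, "cleavage_reads"], sid))
    ranks = {sid: i + 1 for i, sid in enumerate(order)}
    table["efficiency_rank"] = [ranks[sid] for sid in table.index]
    return table


def _track_window_sum(track, chrom: str, lo: int, hi: int) -> float:
    if isinstance(track, StrandedCoverage):
        arr = track.total(chrom)
    else:
        arr = track[chrom]
    lo, hi = max(lo, 0), min(hi, arr.size)
    if lo >= hi:
        return 0.0
    return float(arr[lo:hi].sum())


def classify_repair_pathway(
    rad51_cov,
    xrcc4_cov,
    table: pd.DataFrame,
    w_hr: int = 4000,
    w_nhej: int = 1000,
    k: int = 30,
) -> pd.DataFrame:
    """Label HR-prone / NHEJ-prone sites by the RAD51-to-XRCC4 coverage ratio.

    ``pathway_ratio`` = (RAD51 coverage summed over anchor +/- w_hr) /
    (XRCC4 coverage summed over anchor +/- w_nhej); a zero denominator sorts as
    +infinity. The ``k`` largest ratios become HR_prone, the ``k`` smallest
    NHEJ_prone, the rest stay unlabelled. Ties fall to site_id order.
    """
    n = len(table)
    if 2 * k > n:
        raise ValidationError(f"2k = {2 * k} exceeds number of sites {n}")
    table = table.copy()
    ratios = []
    for sid, row in table.iterrows():
        num = _track_window_sum(rad51_cov, row["chrom"], row["anchor"] - w_hr, row["anchor"] + w_hr)
        den = _track_window_sum(
            xrcc4_cov, row["chrom"], row["anchor"] - w_nhej, row["anchor"] + w_nhej
        )
        ratios.append(num / den if den > 0 else np.inf)
    table["pathway_ratio"] = ratios
    order = sorted(table.index, key=lambda sid: (-table.at[sid, "pathway_ratio"], sid))
    table["pathway"] = "unlabelled"
    table.loc[order[:k], "pathway"] = "HR_prone"
    table.loc[order[-k:], "pathway"] = "NHEJ_prone"
    return table


def classify_transcription_activity(
    sense_baseline: FlankMatrix,
    table: pd.DataFrame,
    quantile: float = 1 / 3,
) -> pd.DataFrame:
    """Split sites into high/low transcription classes by baseline sense coverage.

    The per-site score is the total sense CPM across the flank in the
    undamaged (baseline) condition; the top ``quantile`` fraction is labelled
    ``high``, the bottom ``quantile`` ``low``, the middle stays unlabelled.
    Sites absent from the matrix (e.g. excluded for lacking genes) stay
    unlabelled too.
    """
    if not 0 < quantile <= 0.5:
        raise ValidationError("quantile must be in (0, 0.5]")
    table = table.copy()
    scores = {sid: float(v) for sid, v in zip(sense_baseline.site_ids, sense_baseline.values.sum(axis=1))}
    scored = [sid for sid in table.index if sid in scores]
    table["transcription_class"] = "unlabelled"
    if not scored or all(scores[sid] == 0 for sid in scored):
        logger.warning("all-zero baseline sense matrix: no transcription classes assigned")
        return table
    n_label = int(np.floor(len(scored) * quantile))
    if n_label == 0:
        n_label = 1 if len(scored) >= 2 else 0
    order = sorted(scored, key=lambda sid: (scores[sid], sid))
    table.loc[order[:n_label], "transcription_class"] = "low"
    table.loc[order[len(order) - n_label :], "transcription_class"] = "high"
    return table


@dataclass
class MotifHits:
    """Exact occurrences of a DNA motif; ``strands`` flags forward vs reverse-complement hits."""

    motif: str
    positions: list[int]
    strands: list[str]

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValidationError("empty motif")


def scan_motif(sequence: str, motif: str = ASISI_MOTIF) -> MotifHits:
    """Find all exact, possibly overlapping, occurrences of a motif in a sequence.

    Forward-strand hits are always reported. When the motif is not its own
    reverse complement, reverse-complement occurrences are also reported with
    strand ``-``. The AsiSI recognition motif 5'-GCGATCGC-3' is palindromic,
    so forward scanning is complete for the default.
    """
    if not motif:
        raise ValidationError("empty motif")
    sequence = sequence.upper()
    motif = motif.upper()
    positions: list[int] = []
    strands: list[str] = []

    def _scan(pat: str, strand: str) -> None:
        start = sequence.find(pat)
        while start != -1:
            positions.append(start)
            strands.append(strand)
            start = sequence.find(pat, start + 1)

    _scan(motif, "+")
    rc = reverse_complement(motif)
    if rc != motif:
        _scan(rc, "-")
    order = np.argsort(positions, kind="stable")
    return MotifHits(motif, [positions[i] for i in order], [strands[i] for i in order])
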