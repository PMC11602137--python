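"""Synthetic genomes, genes, DSB sites and stranded read sets with known ground truth.

The generator emulates a sequence-specific DSB-induction experiment read out by
stranded chromatin-associated RNA-seq:

* a small multi-chromosome genome carrying non-overlapping stranded genes with
  lognormally distributed expression levels;
* annotated cut sites placed inside genes (plus a configurable handful of
  deliberately gene-free sites, which exercise the downstream exclusion rule)
  and uncut control sites;
* per-cut-site cleavage efficiencies ``e_s``;
* background sense transcription over genes, and — under damage — bidirectional
  transcription at cut sites whose per-position intensity decays exponentially
  with distance from the anchor, scaled by ``e_s``;
* three conditions: ``no_damage``, ``damage_control`` and ``damage_knockdown``,
  the knockdown amplifying induced transcription with separate sense and
  antisense multipliers (antisense preferentially);
* DSB-capture (bless-like) and repair-factor (rad51/xrcc4-like) read tracks
  with planted intensity orders.

Only the region of interest is simulated; the reported ``library_size`` adds a
configured ``base_library_size`` of notional reads from the rest of the
transcriptome, so induced transcripts remain the small library fraction they
are in a genome-scale library. Every output is a deterministic function of the
configuration and seed. A machine-readable truth record accompanies each
output so planted effects can be checked against recovered ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .coverage import StrandedReadSet
from .io_formats import (
    STRAND_MINUS,
    STRAND_PLUS,
    ChromSizes,
    GeneAnnotation,
    GenomicInterval,
    ValidationError,
    write_gene_annotation_gtf,
    write_intervals,
)

CONDITIONS = ("no_damage", "damage_control", "damage_knockdown")
TRACK_KINDS = ("bless", "rad51", "xrcc4")


@dataclass
class SimulationConfig:
    """All knobs of the generator. Identical config + seed give identical outputs.

    Rates are per library: ``baseline_rate_median`` is the median expected
    number of background reads per kb of gene per library (lognormal across
    genes with log-sd ``baseline_rate_sigma``); ``dart_amplitude`` is the
    expected number of damage-induced reads per strand per site per library at
    cleavage efficiency 1.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 1_500_000
    n_genes: int = 300
    gene_length_min: int = 2_000
    gene_length_max: int = 6_000
    strand_probability: float = 0.5
    gene_gap: int = 200
    n_cut_sites: int = 100
    n_uncut_sites: int = 100
    n_gene_free_sites: int = 3
    site_width: int = 8
    efficiency_min: float = 0.5
    efficiency_max: float = 1.0
    baseline_rate_median: float = 30.0
    baseline_rate_sigma: float = 1.0
    dart_amplitude: float = 1000.0
    decay_length: float = 500.0
    kappa_sense: float = 1.3
    kappa_antisense: float = 2.0
    read_length: int = 100
    replicates: int = 2
    dispersion: str = "poisson"
    nb_size: float = 10.0
    base_library_size: int = 10_000_000
    flank_margin: int = 3_000
    min_anchor_spacing: int = 2_500
    bless_amplitude: float = 200.0
    track_amplitude: float = 100.0
    track_spread: int = 250
    track_read_length: int = 50
    pathway_ratio_log2_span: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency_min <= self.efficiency_max <= 1:
            raise ValidationError("efficiencies must satisfy 0 <= min <= max <= 1")
        if self.decay_length <= 0:
            raise ValidationError("decay_length must be > 0")
        if self.dispersion not in ("poisson", "nb"):
            raise ValidationError("dispersion must be 'poisson' or 'nb'")
        for name in (
            "n_chromosomes", "chromosome_length", "n_genes", "n_cut_sites",
            "n_uncut_sites", "n_gene_free_sites", "replicates", "read_length",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Annotation:
    """Generated genome: genes, sites, chromosome sizes, and the planted truth."""

    config: SimulationConfig
    sizes: ChromSizes
    genes: list[GeneAnnotation]
    gene_rates: dict[str, float]
    sites: list[GenomicInterval]
    site_info: dict[str, dict]

    def truth(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "gene_rates": self.gene_rates,
            "sites": self.site_info,
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sizes.write(outdir / "chrom.sizes")
        write_intervals((g.interval for g in self.genes), outdir / "genes.bed")
        write_intervals(self.sites, outdir / "sites.bed")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth(), fh, indent=1, sort_keys=True)


def _draw_count(rng: np.random.Generator, mean: float, config: SimulationConfig) -> int:
    if mean <= 0:
        return 0
    if config.dispersion == "poisson":
        return int(rng.poisson(mean))
    p = config.nb_size / (config.nb_size + mean)
    return int(rng.negative_binomial(config.nb_size, p))


def _place_nonoverlapping(
    rng: np.random.Generator,
    sizes: ChromSizes,
    lengths: list[int],
    gap: int,
    max_tries: int = 2000,
) -> list[tuple[str, int, int]]:
    chroms = list(sizes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placed = []
    for length in lengths:
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, sizes[chrom] - length))
            end = start + length
            if all(start - gap >= e or end + gap <= s for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise ValidationError(
                "could not place a non-overlapping gene after bounded retries; "
                "increase chromosome_length or reduce n_genes"
            )
    return placed


def generate_annotation(config: SimulationConfig, seed: int) -> Annotation:
    """Generate genome sizes, genes, DSB sites and the truth-record skeleton.

    Genes never overlap (any strand). Cut and uncut sites are anchored inside
    distinct host genes (so each lies within 2.5 kb of at least one gene);
    ``n_gene_free_sites`` extra cut-status sites are placed with no gene within
    2.6 kb, to exercise the orientation-stage exclusion rule. Cleavage
    efficiencies for cut sites are Uniform(efficiency_min, efficiency_max);
    uncut sites have efficiency 0. Planted repair-pathway ratios (a geometric
    ladder spanning ``2**±pathway_ratio_log2_span/2``) are assigned to cut
    sites in random order.
    """
    rng = np.random.default_rng(seed)
    sizes = ChromSizes(
        {f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)}
    )
    n_hosts = config.n_cut_sites + config.n_uncut_sites
    if config.n_genes < n_hosts:
        raise ValidationError("n_genes must be >= n_cut_sites + n_uncut_sites")

    lengths = [
        int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        for _ in range(config.n_genes)
    ]
    spans = _place_nonoverlapping(rng, sizes, lengths, config.gene_gap)
    genes, gene_rates = [], {}
    for i, (chrom, start, end) in enumerate(spans):
        gid = f"gene_{i + 1:04d}"
        strand = STRAND_PLUS if rng.random() < config.strand_probability else STRAND_MINUS
        genes.append(GeneAnnotation(gid, GenomicInterval(chrom, start, end, strand, name=gid)))
        gene_rates[gid] = float(
            config.baseline_rate_median * np.exp(rng.normal(0.0, config.baseline_rate_sigma))
        )

    host_pool = list(rng.permutation(config.n_genes))
    half = config.site_width // 2
    sites: list[GenomicInterval] = []
    site_info: dict[str, dict] = {}
    anchors_by_chrom: dict[str, list[int]] = {c: [] for c in sizes}

    def _spaced(chrom: str, anchor: int) -> bool:
        return all(
            abs(anchor - a) >= config.min_anchor_spacing for a in anchors_by_chrom[chrom]
        )

    def _place_hosted(sid: str, cut_status: str, efficiency: float) -> None:
        # consume host genes from the shuffled pool until an anchor respecting
        # min_anchor_spacing fits inside one of them
        while host_pool:
            host = genes[host_pool.pop(0)]
            iv = host.interval
            for _ in range(50):
                anchor = int(rng.integers(iv.start, iv.end))
                anchor = int(np.clip(anchor, config.flank_margin,
                                     sizes[iv.chrom] - config.flank_margin))
                if _spaced(iv.chrom, anchor):
                    anchors_by_chrom[iv.chrom].append(anchor)
                    _add_site(sid, iv.chrom, anchor, cut_status, efficiency, host)
                    return
        raise ValidationError(
            "could not place sites with the requested min_anchor_spacing; "
            "increase chromosome_length or n_genes, or reduce spacing"
        )

    def _add_site(sid: str, chrom: str, anchor: int, cut_status: str, efficiency: float,
                  host: GeneAnnotation | None) -> None:
        anchor = int(np.clip(anchor, config.flank_margin, sizes[chrom] - config.flank_margin))
        sites.append(
            GenomicInterval(chrom, anchor - half, anchor - half + config.site_width,
                            name=sid, score=f"{efficiency:.4f}")
        )
        site_info[sid] = {
            "chrom": chrom,
            "anchor": anchor,
            "cut_status": cut_status,
            "efficiency": efficiency,
            "gene_free": host is None,
            "host_gene": host.gene_id if host else None,
            "host_strand": host.strand if host else STRAND_PLUS,
            "host_rate": gene_rates[host.gene_id] if host else 0.0,
        }

    for j in range(config.n_cut_sites):
        eff = float(rng.uniform(config.efficiency_min, config.efficiency_max))
        _place_hosted(f"cut_{j + 1:03d}", "cut", eff)
    for j in range(config.n_uncut_sites):
        _place_hosted(f"uncut_{j + 1:03d}", "uncut", 0.0)

    chroms = list(sizes)
    clearance = 2_600
    for j in range(config.n_gene_free_sites):
        for _ in range(10_000):
            chrom = chroms[rng.integers(len(chroms))]
            anchor = int(rng.integers(config.flank_margin, sizes[chrom] - config.flank_margin))
            near_gene = any(
                g.interval.chrom == chrom
                and g.interval.start - clearance < anchor < g.interval.end + clearance
                for g in genes
            )
            if not near_gene and _spaced(chrom, anchor):
                eff = float(rng.uniform(config.efficiency_min, config.efficiency_max))
                anchors_by_chrom[chrom].append(anchor)
                _add_site(f"free_{j + 1:03d}", chrom, anchor, "cut", eff, None)
                break
        else:
            raise ValidationError(
                "could not place a gene-free site after bounded retries; "
                "increase chromosome_length"
            )

    # Planted repair-pathway ratios: geometric ladder over cut sites, shuffled.
    cut_ids = [sid for sid, info in site_info.items() if info["cut_status"] == "cut"]
    span = config.pathway_ratio_log2_span
    ladder = np.power(2.0, np.linspace(-span / 2, span / 2, len(cut_ids)))
    for sid, ratio in zip(rng.permutation(cut_ids), ladder):
        site_info[sid]["planted_pathway_ratio"] = float(ratio)
    for sid, info in site_info.items():
        info.setdefault("planted_pathway_ratio", None)

    return Annotation(config, sizes, genes, gene_rates, sites, site_info)


def _emit_reads(
    rng: np.random.Generator,
    chrom: str,
    centers: np.ndarray,
    strand: str,
    read_length: int,
    chrom_length: int,
) -> list[GenomicInterval]:
    starts = np.rint(centers).astype(int) - read_length // 2
    starts = np.clip(starts, 0, chrom_length - read_length)
    return [GenomicInterval(chrom, int(s), int(s) + read_length, strand) for s in starts]


def simulate_chrRNA(
    annotation: Annotation,
    condition: str,
    replicate: int = 1,
    seed: int = 0,
) -> tuple[StrandedReadSet, dict]:
    """Simulate one stranded chromatin-RNA library for one condition and replicate.

    Background: each gene emits Poisson (or negative-binomial) many reads with
    expectation ``rate * length_kb``, placed uniformly within the gene on its
    own strand. Damage conditions add, at every cleavable site, reads on both
    strands whose centers sit at ``anchor ± Exp(decay_length)`` — i.e. a
    per-position intensity proportional to ``e_s * A * exp(-d / L)``. In the
    knockdown condition the host-strand (sense) induction is multiplied by
    ``kappa_sense`` and the opposite-strand (antisense) induction by
    ``kappa_antisense``. Returns the read set and a truth record holding the
    per-site expected induced read counts.
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    config = annotation.config
    rng = np.random.default_rng([seed, CONDITIONS.index(condition), replicate])
    reads: list[GenomicInterval] = []

    for gene in annotation.genes:
        iv = gene.interval
        rate = annotation.gene_rates[gene.gene_id]
        n = _draw_count(rng, rate * len(iv) / 1000.0, config)
        if n == 0:
            continue
        rl = min(config.read_length, len(iv))
        starts = rng.integers(iv.start, max(iv.start + 1, iv.end - rl + 1), size=n)
        reads.extend(GenomicInterval(iv.chrom, int(s), int(s) + rl, iv.strand) for s in starts)

    mult_sense = mult_anti = 0.0
    if condition == "damage_control":
        mult_sense = mult_anti = 1.0
    elif condition == "damage_knockdown":
        mult_sense, mult_anti = config.kappa_sense, config.kappa_antisense

    truth_sites: dict[str, dict] = {}
    for site in annotation.sites:
        info = annotation.site_info[site.name]
        e_s = info["efficiency"]
        sense_strand = info["host_strand"]
        anti_strand = STRAND_MINUS if sense_strand == STRAND_PLUS else STRAND_PLUS
        exp_sense = e_s * config.dart_amplitude * mult_sense
        exp_anti = e_s * config.dart_amplitude * mult_anti
        truth_sites[site.name] = {
            "expected_induced_sense_reads": exp_sense,
            "expected_induced_antisense_reads": exp_anti,
        }
        if e_s == 0 or condition == "no_damage":
            continue
        chrom_len = annotation.sizes[info["chrom"]]
        for strand, expectation in ((sense_strand, exp_sense), (anti_strand, exp_anti)):
            n = _draw_count(rng, expectation, config)
            if n == 0:
                continue
            d = rng.exponential(config.decay_length, size=n)
            signs = rng.choice((-1.0, 1.0), size=n)
            centers = info["anchor"] + d * signs
            reads.extend(
                _emit_reads(rng, info["chrom"], centers, strand, config.read_length, chrom_len)
            )

    library_size = config.base_library_size + len(reads)
    truth = {
        "condition": condition,
        "replicate": replicate,
        "seed": seed,
        "n_simulated_reads": len(reads),
        "library_size": library_size,
        "planted_log2fc_sense": float(np.log2(config.kappa_sense)),
        "planted_log2fc_antisense": float(np.log2(config.kappa_antisense)),
        "sites": truth_sites,
    }
    return StrandedReadSet(reads, library_size), truth


def simulate_track(
    annotation: Annotation,
    kind: str,
    seed: int = 0,
    noise: str = "poisson",
) -> tuple[StrandedReadSet, dict]:
    """Simulate a DSB-capture (``bless``) or repair-factor ChIP (``rad51``/``xrcc4``) track.

    Reads cluster uniformly within ``anchor ± track_spread``. Bless intensity is
    proportional to the planted cleavage efficiency ``e_s``; rad51 and xrcc4
    intensities realize the planted per-site pathway ratio (rad51 ∝ sqrt(ratio),
    xrcc4 ∝ 1/sqrt(ratio)) at cut sites. ``noise='none'`` emits the rounded
    expectations exactly, for noise-free order-recovery checks.
    """
    if kind not in TRACK_KINDS:
        raise ValidationError(f"unknown track kind {kind!r}; expected one of {TRACK_KINDS}")
    if noise not in ("poisson", "none"):
        raise ValidationError("noise must be 'poisson' or 'none'")
    config = annotation.config
    rng = np.random.default_rng([seed, 1000 + TRACK_KINDS.index(kind)])
    reads: list[GenomicInterval] = []
    truth_sites: dict[str, dict] = {}
    for site in annotation.sites:
        info = annotation.site_info[site.name]
        if kind == "bless":
            expectation = config.bless_amplitude * info["efficiency"]
        else:
            ratio = info["planted_pathway_ratio"]
            if ratio is None:
                expectation = 0.0
            elif kind == "rad51":
                expectation = config.track_amplitude * float(np.sqrt(ratio))
            else:
                expectation = config.track_amplitude / float(np.sqrt(ratio))
        n = int(round(expectation)) if noise == "none" else _draw_count(rng, expectation, config)
        truth_sites[site.name] = {"expected_reads": expectation, "n_reads": n}
        if n == 0:
            continue
        chrom_len = annotation.sizes[info["chrom"]]
        centers = rng.uniform(
            info["anchor"] - config.track_spread, info["anchor"] + config.track_spread, size=n
        )
        reads.extend(
            _emit_reads(rng, info["chrom"], centers, STRAND_PLUS,
                        config.track_read_length, chrom_len)
        )
    truth = {"kind": kind, "noise": noise, "seed": seed, "sites": truth_sites}
    return StrandedReadSet(reads, max(len(reads), 1)), truth
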